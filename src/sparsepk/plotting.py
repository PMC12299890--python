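"""Concentration-time figures: per-subject spaghetti and pooled mean ± SEM."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # file output only; no display backend assumed

import matplotlib.pyplot as plt
import numpy as np

from .io import SubjectProfile


def _save(fig, outdir: Path, stem: str, formats: Sequence[str]) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fmt in formats:
        path = outdir / f"{stem}.{fmt}"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    return paths


def plot_profiles(
    profiles: Sequence[SubjectProfile],
    outdir: str | Path,
    *,
    stem: str = "profiles",
    pooled: bool = False,
    formats: Sequence[str] = ("png", "svg"),
) -> list[Path]:
    """Write concentration-time plots; returns the files written.

    With ``pooled=False`` each subject is a line+marker series. With
    ``pooled=True`` the mean over subjects sampled at each time is drawn
    with SEM error bars (bars omitted where only one subject contributes,
    or for a single-point profile).
    """
    if not profiles:
        raise ValueError("no profiles to plot")
    outdir = Path(outdir)
    fig, ax = plt.subplots(figsize=(6, 4))
    if pooled:
        times = sorted({p.time_h for prof in profiles for p in prof.points})
        means, sems = [], []
        for t in times:
            vals = [p.conc_mg_per_L for prof in profiles for p in prof.points if p.time_h == t]
            means.append(float(np.mean(vals)))
            sems.append(
                float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        ax.errorbar(times, means, yerr=sems, fmt="o-", capsize=3, color="tab:blue")
        ax.set_title(f"Mean ± SEM serum profile (n={len(profiles)} subjects)")
    else:
        for prof in profiles:
            style = "o" if len(prof.points) == 1 else "o-"
            ax.plot(prof.times, prof.concentrations, style, label=prof.subject_id)
        ax.legend(fontsize=8)
        ax.set_title("Individual serum concentration-time profiles")
    ax.set_xlabel("Time after dose (h)")
    ax.set_ylabel("Concentration (mg/L)")
    return _save(fig, outdir, stem, formats)
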