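"""Minimal plotting helper for the TSS-distance profile."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .genes import TSSDistanceProfile


def plot_tss_profile(profile: TSSDistanceProfile, path: str | Path) -> None:
    """Bar chart of peak counts per signed TSS-distance bin."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(range(len(profile.labels)), profile.counts, color="#4878a8")
    ax.set_xticks(range(len(profile.labels)))
    ax.set_xticklabels(profile.labels, rotation=45, ha="right")
    ax.set_ylabel("peaks")
    ax.set_xlabel("signed distance to nearest TSS")
    ax.set_title(f"TSS distance profile (n={profile.n_total})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
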