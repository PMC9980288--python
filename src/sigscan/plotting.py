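"""Basic profile charts: 96-context spectrum bars and quintile profiles.

Matplotlib is imported lazily so the rest of the package works without a
plotting backend.
"""

from __future__ import annotations

from .spectrum import SBS96_LABELS, Spectrum96
from .timing import QuintileProfile

#: Conventional substitution-type colors (C>A .. T>G).
_SUB_COLORS = ("#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63", "#EBC5C4")


def plot_spectrum(spectrum: Spectrum96, ax=None):
    """Bar chart of a 96-context spectrum in catalog order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    counts = [spectrum.counts[label] for label in SBS96_LABELS]
    colors = [_SUB_COLORS[i // 16] for i in range(96)]
    ax.bar(range(96), counts, color=colors, width=0.8)
    ax.set_xticks(range(96))
    ax.set_xticklabels(
        [f"{l[0]}{l[2]}{l[6]}" for l in SBS96_LABELS], rotation=90, fontsize=5
    )
    for i in range(1, 6):
        ax.axvline(i * 16 - 0.5, color="grey", lw=0.5)
    sub_types = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    for i, sub in enumerate(sub_types):
        ax.text(i * 16 + 8, 1.02, sub, transform=ax.get_xaxis_transform(),
                ha="center", color=_SUB_COLORS[i])
    ax.set_ylabel("mutations")
    ax.set_title(f"{spectrum.sample_id} (n={spectrum.total})", loc="left")
    return ax


def plot_quintile_profile(profile: QuintileProfile, ax=None, tc_tt: bool = False):
    """Bar chart of largest-quintile-normalized densities (or TC>TT
    percentages with ``tc_tt``) from early- to late-replicating."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    values = profile.tc_tt_percent if tc_tt else profile.normalized
    ax.bar(range(1, 6), values, color="#4C72B0")
    ax.set_xticks(range(1, 6))
    ax.set_xlabel("replication-timing quintile (1 = earliest)")
    ax.set_ylabel("% TC>TT of SBS" if tc_tt else "normalized mutation density")
    ax.set_title(profile.group_id, loc="left")
    return ax
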