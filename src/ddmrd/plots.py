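"""QC plotting: 2D amplitude scatter of a well with its gates."""

from __future__ import annotations

from .classify import GateSet
from .containers import DropletWell


def plot_well(well: DropletWell, gates: GateSet | None = None, ax=None):
    """Scatter HEX (x) vs FAM (y) amplitudes; overlay gates if given.

    Returns the matplotlib Axes. Import of matplotlib is deferred so the
    analysis stack stays usable headless without it configured.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(well.hex, well.fam, s=2, alpha=0.4, linewidths=0, color="#555555")
    if gates is not None:
        ax.axhline(gates.fam_threshold, color="tab:red", lw=0.8, ls="--")
        ax.axvline(gates.hex_threshold, color="tab:green", lw=0.8, ls="--")
        for g in gates.target_gates:
            ax.axhspan(g.fam_low, g.fam_high, color="tab:blue", alpha=0.08)
            ax.text(
                ax.get_xlim()[0], g.fam_high, g.target_id, fontsize=7, va="bottom"
            )
    ax.set_xlabel("HEX amplitude (a.u.)")
    ax.set_ylabel("FAM amplitude (a.u.)")
    ax.set_title(f"{well.sample_id} [{well.well_id}]")
    return ax
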