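"""Minimal plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .landscape import COMTrack, InteractionMap

__all__ = ["plot_com_track", "plot_interaction_map"]


def plot_com_track(track: COMTrack, path) -> None:
    """x-y scatter of the helix COM, shaded by z."""
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(track.x, track.y, c=track.z, s=6, cmap="gray")
    fig.colorbar(sc, ax=ax, label="z (A)")
    ax.set_xlabel("x (A)")
    ax.set_ylabel("y (A)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_interaction_map(imap: InteractionMap, path, component: str = "total") -> None:
    """Residue-pair energy heat map."""
    mat = getattr(imap, component)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        mat,
        aspect="auto",
        origin="lower",
        cmap="coolwarm",
        extent=[
            imap.resids_b.min() - 0.5,
            imap.resids_b.max() + 0.5,
            imap.resids_a.min() - 0.5,
            imap.resids_a.max() + 0.5,
        ],
    )
    fig.colorbar(im, ax=ax, label="energy (kcal/mol)")
    ax.set_xlabel("residue (set B)")
    ax.set_ylabel("residue (set A)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
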