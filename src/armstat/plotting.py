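"""Optional PNG previews of the reproduced tables.

Kept out of the computational core: importing this module requires
matplotlib, and nothing in the library or tests depends on it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import RunConfig, read_csv

__all__ = ["render_previews"]


def render_previews(config: RunConfig) -> list[Path]:
    """Render one PNG per emitted CSV family under the run's output directory."""
    out = Path(config.out_dir)
    written: list[Path] = []

    for name, varying in (("fig2_shoulder_family", "alpha_s"),
                          ("fig3_elbow_family", "alpha_e")):
        df = read_csv(out / f"{name}.csv")
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax, col, title in zip(
            axes, ["gamma_s", "gamma_e", "gamma_diff"],
            ["gamma_s", "gamma_e", "gamma_e - gamma_s"],
        ):
            for k, line in df.groupby("fixed_index"):
                line = line.sort_values("varying_index")
                ax.plot(line[varying], line[col], marker="o", ms=2, lw=0.8)
            ax.set_xlabel(f"{varying} (rad)")
            ax.set_ylabel(f"{title} (rad)")
        fig.tight_layout()
        path = out / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    weights = read_csv(out / "fig6_weights.csv")
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(weights["alpha_e"], weights["w_tcd"], marker="o", label="w_TCD")
    ax.plot(weights["alpha_e"], weights["w_tod"], marker="s", label="w_TOD")
    ax.set_xlabel("alpha_e (rad)")
    ax.set_ylabel("sector weight")
    ax.legend()
    fig.tight_layout()
    path = out / "fig6_weights.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
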