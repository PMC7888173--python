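"""Optional Manhattan and QQ plotting helpers for meta-analysis scans."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .datatypes import ProbeManifest  # noqa: E402
from .meta import MetaResult  # noqa: E402


def manhattan_plot(meta: MetaResult, manifest: ProbeManifest, path) -> None:
    """Genome-wide -log10 p by position, Bonferroni threshold as a line."""
    t = meta.table.join(manifest.table[["chrom", "pos"]])
    t["chrom_num"] = t["chrom"].str.removeprefix("chr").astype(int)
    t = t.sort_values(["chrom_num", "pos"])
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(10, 3.5))
    for i, (_, grp) in enumerate(t.groupby("chrom_num", sort=True)):
        ax.scatter(
            x[t["chrom_num"] == grp["chrom_num"].iloc[0]],
            -np.log10(grp["p"]),
            s=3,
            color="C0" if i % 2 else "C1",
            rasterized=False,
        )
    ax.axhline(-np.log10(meta.bonferroni_threshold), color="red", lw=1)
    ax.set_xlabel("probe (by genomic order)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(pvalues, path, lam: float | None = None) -> None:
    """Observed vs expected -log10 p quantiles."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(p)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(exp, obs, s=4)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    if lam is not None:
        ax.set_title(f"lambda = {lam:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
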