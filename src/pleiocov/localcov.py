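"""Local genetic (co)variance posteriors per LD window, significance, loci.

For window w and retained draw s, the local variances and covariance are the
sample moments (n-1 denominator) over individuals of the window-limited
genetic scores:

    V1_w^(s)  = Var(X_w beta_w1^(s))
    V2_w^(s)  = Var(X_w beta_w2^(s))
    Cov_w^(s) = Cov(X_w beta_w1^(s), X_w beta_w2^(s))

computed here through the algebraically identical quadratic forms
beta' S_w beta with S_w the sample covariance of member dosages.  Summaries
are posterior means, SDs, and equal-tailed 95% credible regions; a window is
flagged significant when its covariance CR excludes zero.  Significant windows
sharing at least one member SNP are merged (transitive closure) into loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WindowEstimate",
    "Locus",
    "window_cov_draws",
    "summarize_window",
    "merge_significant_windows",
    "write_results",
    "read_windows_table",
]

_QUANTITIES = ("V1", "V2", "Cov")


@dataclass(eq=False)
class WindowEstimate:
    """Posterior summary of (V1, V2, Cov) for one window.

    Values are in squared-trait units; reports scale them (x 1e4 by default).
    """

    window: object
    post_mean: dict
    post_sd: dict
    cr_low: dict
    cr_high: dict
    level: float
    significant: bool

    @property
    def n_snps(self) -> int:
        return self.window.n_snps


@dataclass(eq=False)
class Locus:
    """A merged run of significant windows on one chromosome."""

    windows: list
    chromosome: int
    bp_start: int
    bp_end: int
    representative: WindowEstimate   # largest |posterior mean Cov|
    direction: int                   # sign of the representative covariance

    @property
    def member_snps(self) -> np.ndarray:
        return np.unique(np.concatenate([w.window.member_indices for w in self.windows]))


def window_cov_draws(X_w: np.ndarray, beta_draws_w: np.ndarray) -> np.ndarray:
    """Per-draw (V1, V2, Cov) triples for one window.

    ``X_w``: individuals x m member dosages (imputed, centered);
    ``beta_draws_w``: retained x m x 2 effect draws for those same SNPs.
    Returns a retained x 3 array.
    """
    X_w = np.asarray(X_w, dtype=np.float64)
    B = np.asarray(beta_draws_w, dtype=np.float64)
    if B.ndim != 3 or B.shape[2] != 2 or B.shape[1] != X_w.shape[1]:
        raise ValueError(
            f"beta draws have shape {B.shape} but window has {X_w.shape[1]} SNPs"
        )
    n = X_w.shape[0]
    Xc = X_w - X_w.mean(axis=0)
    S_w = (Xc.T @ Xc) / (n - 1)
    B1 = B[:, :, 0]
    B2 = B[:, :, 1]
    out = np.empty((B.shape[0], 3))
    SB1 = B1 @ S_w
    out[:, 0] = np.einsum("sj,sj->s", SB1, B1)
    out[:, 1] = np.einsum("sj,sj->s", B2 @ S_w, B2)
    out[:, 2] = np.einsum("sj,sj->s", SB1, B2)
    return out


def summarize_window(window, draws: np.ndarray, level: float = 0.95) -> WindowEstimate:
    """Posterior mean, SD, and equal-tailed CR per quantity; significance when
    the covariance CR excludes zero."""
    draws = np.asarray(draws, dtype=np.float64)
    if draws.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws to summarize")
    if not np.all(np.isfinite(draws)):
        raise ValueError(f"non-finite (co)variance draws in window {window.key()}")
    alpha = (1.0 - level) / 2.0
    mean = {}
    sd = {}
    lo = {}
    hi = {}
    for q, name in enumerate(_QUANTITIES):
        col = draws[:, q]
        mean[name] = float(col.mean())
        sd[name] = float(col.std(ddof=1))
        lo[name] = float(np.quantile(col, alpha))
        hi[name] = float(np.quantile(col, 1.0 - alpha))
    significant = lo["Cov"] > 0.0 or hi["Cov"] < 0.0
    return WindowEstimate(
        window=window, post_mean=mean, post_sd=sd, cr_low=lo, cr_high=hi,
        level=level, significant=significant,
    )


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_significant_windows(estimates, panel=None) -> list:
    """Transitive closure of "shares >= 1 member SNP" over significant windows.

    ``estimates`` must already be restricted to significant windows.  Returns
    loci ordered by (chromosome, bp start); each carries the member window
    with the largest |posterior mean Cov| as its representative, and that
    covariance's sign as the locus direction.
    """
    ests = list(estimates)
    if not ests:
        return []
    uf = _UnionFind(len(ests))
    by_snp: dict = {}
    for i, e in enumerate(ests):
        for s in e.window.member_indices.tolist():
            if s in by_snp:
                uf.union(by_snp[s], i)
            else:
                by_snp[s] = i
    groups: dict = {}
    for i in range(len(ests)):
        groups.setdefault(uf.find(i), []).append(ests[i])
    loci = []
    for members in groups.values():
        rep = max(members, key=lambda e: abs(e.post_mean["Cov"]))
        snps = np.unique(np.concatenate([e.window.member_indices for e in members]))
        if panel is not None:
            pos = panel.snp_map["pos"].to_numpy()
            chrom = int(panel.snp_map["chrom"].iat[int(snps[0])])
            bp0, bp1 = int(pos[snps[0]]), int(pos[snps[-1]])
        else:
            chrom, bp0, bp1 = 0, int(snps[0]), int(snps[-1])
        loci.append(
            Locus(
                windows=sorted(members, key=lambda e: int(e.window.member_indices[0])),
                chromosome=chrom,
                bp_start=bp0,
                bp_end=bp1,
                representative=rep,
                direction=int(np.sign(rep.post_mean["Cov"])),
            )
        )
    loci.sort(key=lambda L: (L.chromosome, L.bp_start))
    return loci


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def estimates_to_frame(estimates, panel, scale: float = 1e4) -> pd.DataFrame:
    snp = panel.snp_map["snp"]
    chrom = panel.snp_map["chrom"].to_numpy()
    pos = panel.snp_map["pos"].to_numpy()
    rows = []
    for e in estimates:
        mem = e.window.member_indices
        row = {
            "chrom": int(chrom[mem[0]]),
            "bp_start": int(pos[mem[0]]),
            "bp_end": int(pos[mem[-1]]),
            "first_snp": snp.iat[int(mem[0])],
            "last_snp": snp.iat[int(mem[-1])],
            "seed_snp": snp.iat[int(e.window.seed_index)],
            "n_snps": e.n_snps,
        }
        for name in _QUANTITIES:
            row[f"{name}_mean"] = _fmt(e.post_mean[name] * scale)
            row[f"{name}_sd"] = _fmt(e.post_sd[name] * scale)
            row[f"{name}_cr_low"] = _fmt(e.cr_low[name] * scale)
            row[f"{name}_cr_high"] = _fmt(e.cr_high[name] * scale)
        row["significant"] = int(e.significant)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(estimates, loci, panel, outdir, scale: float = 1e4) -> dict:
    """Write the windows TSV (+BED) and loci TSV; returns the paths.

    Estimates and CRs are multiplied by ``scale`` (1e4 by default) for
    readability; the scale is recorded in a header comment line.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# local (co)variance estimates multiplied by {scale:g}\n"

    win_path = outdir / "windows.tsv"
    wf = estimates_to_frame(estimates, panel, scale)
    with open(win_path, "w") as fh:
        fh.write(header)
        wf.to_csv(fh, sep="\t", index=False)

    bed_path = outdir / "windows.bed"
    with open(bed_path, "w") as fh:
        for e in estimates:
            mem = e.window.member_indices
            c = int(panel.snp_map["chrom"].iat[int(mem[0])])
            b0 = int(panel.snp_map["pos"].iat[int(mem[0])]) - 1
            b1 = int(panel.snp_map["pos"].iat[int(mem[-1])])
            fh.write(f"{c}\t{b0}\t{b1}\twin_{mem[0]}_{mem[-1]}\n")

    loci_path = outdir / "loci.tsv"
    with open(loci_path, "w") as fh:
        fh.write(header)
        fh.write("chrom\tbp_start\tbp_end\tn_windows\tn_snps\tfirst_snp\tlast_snp\t"
                 "cov\tcov_cr_low\tcov_cr_high\tdirection\n")
        snp = panel.snp_map["snp"]
        for L in loci:
            rep = L.representative
            snps = L.member_snps
            fh.write(
                f"{L.chromosome}\t{L.bp_start}\t{L.bp_end}\t{len(L.windows)}\t"
                f"{len(snps)}\t{snp.iat[int(snps[0])]}\t{snp.iat[int(snps[-1])]}\t"
                f"{_fmt(rep.post_mean['Cov'] * scale)}\t"
                f"{_fmt(rep.cr_low['Cov'] * scale)}\t"
                f"{_fmt(rep.cr_high['Cov'] * scale)}\t{L.direction}\n"
            )
    return {"windows": win_path, "bed": bed_path, "loci": loci_path}


def read_windows_table(path) -> pd.DataFrame:
    """Read back a windows TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
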