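"""Chromosomal segmentation: non-overlapping SNP cores with overlapping flanks.

Each chromosome is tiled by consecutive cores of ``core_size`` SNPs (the last
core takes the remainder).  Each segment additionally carries up to
``flank_size`` buffer SNPs on each side; flanks absorb LD with neighbouring
cores and are clipped at chromosome boundaries, never wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["Segment", "make_segments", "segments_to_table"]


@dataclass(frozen=True)
class Segment:
    """Half-open SNP-index intervals in panel coordinates."""

    chromosome: int
    core: tuple          # [start, end)
    left_flank: tuple    # [start, end), end == core[0]
    right_flank: tuple   # [start, end), start == core[1]

    @property
    def start(self) -> int:
        return self.left_flank[0]

    @property
    def stop(self) -> int:
        return self.right_flank[1]

    @property
    def indices(self) -> range:
        """All SNP indices covered (flanks + core), in map order."""
        return range(self.start, self.stop)

    @property
    def core_indices(self) -> range:
        return range(*self.core)


def make_segments(panel, core_size: int = 1000, flank_size: int = 250):
    """Partition ``panel``'s SNPs into segments, per chromosome.

    Cores tile each chromosome exactly once; flanks of segment k fall inside
    the cores of segments k-1 / k+1 where those exist.
    """
    if core_size < 1:
        raise ValueError("core_size must be >= 1")
    if flank_size < 0:
        raise ValueError("flank_size must be >= 0")
    chrom = panel.snp_map["chrom"].to_numpy()
    segments = []
    for c in panel.chromosomes():
        idx = (chrom == c).nonzero()[0]
        lo, hi = int(idx[0]), int(idx[-1]) + 1  # snp_map sorted -> contiguous run
        for start in range(lo, hi, core_size):
            end = min(start + core_size, hi)
            segments.append(
                Segment(
                    chromosome=int(c),
                    core=(start, end),
                    left_flank=(max(start - flank_size, lo), start),
                    right_flank=(end, min(end + flank_size, hi)),
                )
            )
    return segments


def segments_to_table(segments, panel) -> pd.DataFrame:
    """BED-like audit table: chromosome, core bp span, core/flank index spans."""
    pos = panel.snp_map["pos"].to_numpy()
    rows = []
    for s in segments:
        rows.append(
            {
                "chrom": s.chromosome,
                "core_bp_start": int(pos[s.core[0]]),
                "core_bp_end": int(pos[s.core[1] - 1]),
                "core_start": s.core[0],
                "core_end": s.core[1],
                "left_flank_start": s.left_flank[0],
                "left_flank_end": s.left_flank[1],
                "right_flank_start": s.right_flank[0],
                "right_flank_end": s.right_flank[1],
            }
        )
    return pd.DataFrame(rows)
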