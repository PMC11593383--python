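"""Genomic inbreeding from runs of homozygosity (F_ROH).

F_ROH for one individual is the summed bp length of its ROH divided by the
length of the genome considered.  The default denominator is the map-covered
autosomal length — the sum over autosomes of (last SNP position − first SNP
position) — so numerator and denominator refer to the same chip; a fixed
assembly length in bp may be supplied instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .engine import RohSet
from .io import GenotypeDataset


def genome_length_from_map(snp_map: pd.DataFrame, autosomes_only: bool = True) -> int:
    """Map-covered genome length: sum per chromosome of last − first SNP bp.

    Chromosomes with a single marker span 0 bp and trigger a warning.
    """
    if len(snp_map) == 0:
        raise ValueError("empty map")
    total = 0
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        if autosomes_only:
            try:
                if int(chrom) <= 0:
                    continue
            except (ValueError, TypeError):
                continue
        pos = grp["pos"].to_numpy()
        if len(pos) == 1:
            warnings.warn(f"chromosome {chrom!r} has a single marker; contributes 0 bp")
            continue
        total += int(pos.max() - pos.min())
    if total == 0 and autosomes_only:
        raise ValueError("no autosomal span in map")
    return total


def compute_froh(roh: RohSet | pd.DataFrame, genome_length_bp: int,
                 samples: pd.DataFrame, by_class: bool = False) -> pd.DataFrame:
    """Per-individual F_ROH records.

    ``samples`` must contain every sample appearing in ``roh`` (columns
    ``sample`` and ``population``); samples without any ROH get F_ROH = 0.
    With ``by_class=True`` an additional ``froh_<class>`` column is added per
    length class (class-wise partition of the genomic inbreeding).
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    seg = roh.segments if isinstance(roh, RohSet) else roh
    known = set(samples["sample"])
    unknown = set(seg["sample"]) - known
    if unknown:
        raise ValueError(f"ROH refer to unknown samples: {sorted(unknown)[:3]}")
    sums = seg.groupby("sample")["length_bp"].sum()
    counts = seg.groupby("sample").size()
    out = samples[["sample", "population"]].copy()
    out["n_roh"] = out["sample"].map(counts).fillna(0).astype(int)
    out["sum_roh_bp"] = out["sample"].map(sums).fillna(0).astype(np.int64)
    out["genome_length_bp"] = int(genome_length_bp)
    out["froh"] = out["sum_roh_bp"] / genome_length_bp
    if (out["froh"] > 1.0).any():
        raise ValueError("F_ROH above 1: overlapping segments or wrong denominator")
    if by_class:
        per = seg.pivot_table(index="sample", columns="class", values="length_bp",
                              aggfunc="sum", fill_value=0)
        for lab in per.columns:
            out[f"froh_{lab}"] = out["sample"].map(per[lab]).fillna(0) / genome_length_bp
    return out


def summarize_froh(records: pd.DataFrame, by: str = "population") -> pd.DataFrame:
    """Per-group summary of F_ROH (mean, sd, quartiles), ordered by
    descending mean — the box-plot-ready view."""
    g = records.groupby(by)["froh"]
    out = pd.DataFrame({
        "n": g.size(),
        "mean": g.mean(),
        "sd": g.std(ddof=1).fillna(0.0),
        "min": g.min(),
        "q25": g.quantile(0.25),
        "median": g.median(),
        "q75": g.quantile(0.75),
        "max": g.max(),
    })
    return out.sort_values("mean", ascending=False).reset_index()


def froh_for_dataset(ds: GenotypeDataset, roh: RohSet,
                     genome_length_bp: int | None = None,
                     by_class: bool = False) -> pd.DataFrame:
    """F_ROH for every sample of ``ds`` using its map span as denominator
    unless an explicit ``genome_length_bp`` override is given."""
    if genome_length_bp is None:
        genome_length_bp = genome_length_from_map(ds.snp_map)
    return compute_froh(roh, genome_length_bp, ds.samples, by_class=by_class)
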