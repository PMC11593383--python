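"""ROH islands: per-population SNP-in-ROH incidence, z-score thresholds,
island calling and cross-population sharing.

For each population a presence–absence matrix of SNPs inside ROH is reduced
to a per-SNP incidence percentage (share of individuals whose ROH cover the
SNP).  Incidence percentages are standardised over all autosomal SNPs of the
population and SNPs in the extreme upper tail of the standard-normal
distribution (default one-sided p < 1e-5, z >= 4.2649) mark islands —
regions of exceptional homozygosity interpreted as selection signatures or
shared ancestry.  Significant SNPs close together are merged into island
regions, and islands from different populations whose spans overlap are
grouped into shared regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import RohSet
from .io import GenotypeDataset


@dataclass(frozen=True)
class IslandConfig:
    """Island-calling parameters.

    ``tail_fraction`` is the one-sided upper-tail p-value cutoff on the
    incidence z-score (1e-5 keeps the extreme 0.001% of the distribution);
    ``two_sided`` switches to a two-sided cutoff.  Consecutive significant
    SNPs at most ``merge_gap_bp`` apart are merged into one island; islands
    with fewer than ``min_island_snps`` significant SNPs are dropped.
    ``per_chromosome_norm`` standardises incidence within each chromosome
    instead of pooling all autosomes.
    """

    tail_fraction: float = 1e-5
    merge_gap_bp: int = 500_000
    min_island_snps: int = 2
    two_sided: bool = False
    per_chromosome_norm: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")
        if self.merge_gap_bp < 0:
            raise ValueError("merge_gap_bp must be >= 0")
        if self.min_island_snps < 1:
            raise ValueError("min_island_snps must be >= 1")

    @property
    def z_critical(self) -> float:
        p = self.tail_fraction / 2 if self.two_sided else self.tail_fraction
        return float(stats.norm.isf(p))


@dataclass
class IslandScan:
    """Per-SNP incidence scan for one population.

    ``table`` columns: ``chrom``, ``snp``, ``pos``, ``count``, ``pct``,
    ``z``, ``significant``.  ``threshold_pct`` is the minimum incidence
    percentage attained by any significant SNP (NaN when none is).
    """

    population: str
    population_size: int
    table: pd.DataFrame
    mean_pct: float
    sd_pct: float
    z_critical: float
    threshold_pct: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def incidence_matrix(roh: RohSet | pd.DataFrame, snp_map: pd.DataFrame,
                     samples: pd.DataFrame, population: str) -> pd.DataFrame:
    """Per-SNP count of a population's individuals covered by an ROH.

    A SNP is covered by an individual when one of that individual's segments
    on the same chromosome spans the SNP position (segments of one individual
    never overlap, so summing segment indicators counts individuals).
    Only autosomal markers are scanned.  Returns a frame with columns
    ``chrom``, ``snp``, ``pos``, ``count``.
    """
    seg = roh.segments if isinstance(roh, RohSet) else roh
    pop_samples = samples.loc[samples["population"] == population, "sample"]
    if pop_samples.empty:
        raise ValueError(f"population {population!r} has no samples")
    seg = seg[seg["sample"].isin(set(pop_samples))]

    out = []
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        try:
            if int(chrom) <= 0:
                continue
        except (ValueError, TypeError):
            continue
        pos = grp["pos"].to_numpy()
        counts = np.zeros(len(pos), dtype=np.int64)
        sub = seg[seg["chrom"] == chrom]
        starts = np.searchsorted(pos, sub["start_bp"].to_numpy(), side="left")
        ends = np.searchsorted(pos, sub["end_bp"].to_numpy(), side="right") - 1
        for i0, i1 in zip(starts, ends):
            if i1 >= i0:
                counts[i0:i1 + 1] += 1
        out.append(pd.DataFrame({"chrom": chrom, "snp": grp["snp"].to_numpy(),
                                 "pos": pos, "count": counts}))
    if not out:
        raise ValueError("map has no autosomal markers")
    return pd.concat(out, ignore_index=True)


def zscore_scan(counts: pd.DataFrame, population_size: int,
                cfg: IslandConfig = IslandConfig(),
                population: str = "") -> IslandScan:
    """Standardise per-SNP incidence and flag upper-tail outliers.

    The mean and sd are computed over all autosomal SNPs (or per chromosome
    with ``cfg.per_chromosome_norm``).  A zero sd (uniform incidence) yields
    no significant SNPs and a warning.
    """
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    tbl = counts.copy()
    tbl["pct"] = tbl["count"] / population_size * 100.0

    def _z(v: np.ndarray) -> tuple[np.ndarray, float, float]:
        mean = float(v.mean())
        sd = float(v.std(ddof=0))
        if sd == 0.0:
            warnings.warn("incidence is uniform (sd = 0); no islands can be called")
            return np.zeros_like(v), mean, sd
        return (v - mean) / sd, mean, sd

    if cfg.per_chromosome_norm:
        zs = np.empty(len(tbl))
        for _, grp in tbl.groupby("chrom", sort=False):
            z, _, _ = _z(grp["pct"].to_numpy())
            zs[grp.index.to_numpy()] = z
        mean = float(tbl["pct"].mean())
        sd = float(tbl["pct"].std(ddof=0))
        tbl["z"] = zs
    else:
        z, mean, sd = _z(tbl["pct"].to_numpy())
        tbl["z"] = z
    zc = cfg.z_critical
    tbl["significant"] = (np.abs(tbl["z"]) if cfg.two_sided else tbl["z"]) >= zc
    if sd == 0.0:
        tbl["significant"] = False
    thr = float(tbl.loc[tbl["significant"], "pct"].min()) if tbl["significant"].any() else float("nan")
    return IslandScan(population=population, population_size=population_size,
                      table=tbl, mean_pct=mean, sd_pct=sd, z_critical=zc,
                      threshold_pct=thr)


ISLAND_COLUMNS = ["population", "chrom", "start_bp", "end_bp",
                  "n_significant_snp", "n_total_snp", "min_pct", "max_z"]


def call_islands(scan: IslandScan, snp_map: pd.DataFrame,
                 cfg: IslandConfig = IslandConfig()) -> pd.DataFrame:
    """Merge significant SNPs into island regions.

    Consecutive significant SNPs on one chromosome at most
    ``cfg.merge_gap_bp`` apart join one island; bounds are the first/last
    significant SNP positions.  Both the significant-SNP count and the total
    marker count inside the bounds are reported (the field convention for
    "nSNP" is ambiguous between the two).
    """
    sig = scan.significant()
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        if pos.size == 0:
            continue
        split = np.flatnonzero(np.diff(pos) > cfg.merge_gap_bp)
        for piece in np.split(pos, split + 1):
            if piece.size < cfg.min_island_snps:
                continue
            chrom_pos = snp_map.loc[snp_map["chrom"] == chrom, "pos"].to_numpy()
            n_total = int(np.searchsorted(chrom_pos, piece[-1], side="right")
                          - np.searchsorted(chrom_pos, piece[0], side="left"))
            sub = grp[(grp["pos"] >= piece[0]) & (grp["pos"] <= piece[-1])]
            rows.append(dict(population=scan.population, chrom=chrom,
                             start_bp=int(piece[0]), end_bp=int(piece[-1]),
                             n_significant_snp=int(piece.size), n_total_snp=n_total,
                             min_pct=float(sub["pct"].min()), max_z=float(sub["z"].max())))
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def shared_islands(per_population_islands: pd.DataFrame,
                   all_populations: list[str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group islands from different populations into shared regions.

    Islands on one chromosome whose bp intervals overlap (transitively, any
    >= 1 bp overlap) form one region spanning their union, labelled with the
    set of member populations (``All`` when every analysed population is
    present).  Returns ``(regions, memberships)``: one row per region, and a
    long-form table with one row per member island so that per-population
    island counts are preserved.
    """
    isl = per_population_islands.reset_index(drop=True)
    regions_rows, member_rows = [], []
    region_id = 0
    for chrom, grp in isl.groupby("chrom", sort=False):
        grp = grp.sort_values(["start_bp", "end_bp"], kind="stable")
        cur: list[int] = []
        cur_end = -1
        clusters: list[list[int]] = []
        for idx, r in grp.iterrows():
            if cur and r["start_bp"] > cur_end:
                clusters.append(cur)
                cur = []
                cur_end = -1
            cur.append(idx)
            cur_end = max(cur_end, int(r["end_bp"]))
        if cur:
            clusters.append(cur)
        for members in clusters:
            sub = isl.loc[members]
            pops = sorted(set(sub["population"]))
            if all_populations is not None and set(pops) == set(all_populations):
                pop_label = "All"
            else:
                pop_label = ", ".join(pops)
            regions_rows.append(dict(region_id=region_id, chrom=chrom,
                                     start_bp=int(sub["start_bp"].min()),
                                     end_bp=int(sub["end_bp"].max()),
                                     populations=pop_label,
                                     n_populations=len(pops),
                                     n_member_islands=len(members),
                                     n_significant_snp=int(sub["n_significant_snp"].sum())))
            for idx in members:
                member_rows.append(dict(region_id=region_id,
                                        population=isl.loc[idx, "population"],
                                        chrom=chrom,
                                        start_bp=int(isl.loc[idx, "start_bp"]),
                                        end_bp=int(isl.loc[idx, "end_bp"])))
            region_id += 1
    regions = pd.DataFrame(regions_rows, columns=["region_id", "chrom", "start_bp",
                                                  "end_bp", "populations", "n_populations",
                                                  "n_member_islands", "n_significant_snp"])
    memberships = pd.DataFrame(member_rows, columns=["region_id", "population",
                                                     "chrom", "start_bp", "end_bp"])
    return regions, memberships


def island_scan_for_population(ds: GenotypeDataset, roh: RohSet, population: str,
                               cfg: IslandConfig = IslandConfig()) -> IslandScan:
    """Incidence + z-scan for one population of a dataset."""
    counts = incidence_matrix(roh, ds.snp_map, ds.samples, population)
    n = int((ds.samples["population"] == population).sum())
    return zscore_scan(counts, n, cfg, population=population)


def find_islands(ds: GenotypeDataset, roh: RohSet,
                 cfg: IslandConfig = IslandConfig()
                 ) -> tuple[dict[str, IslandScan], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full island stage for every population.

    Returns ``(scans, islands, regions, memberships)``.
    """
    scans: dict[str, IslandScan] = {}
    pieces = []
    pops = ds.populations()
    for pop in pops:
        scan = island_scan_for_population(ds, roh, pop, cfg)
        scans[pop] = scan
        pieces.append(call_islands(scan, ds.snp_map, cfg))
    islands = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(columns=ISLAND_COLUMNS)
    regions, memberships = shared_islands(islands, all_populations=pops)
    return scans, islands, regions, memberships
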