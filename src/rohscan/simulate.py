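"""Synthetic SNP-array genotypes with planted autozygosity ground truth.

The generator emulates the structure the pipeline assumes in real data:
multi-chromosome biallelic maps at high-density-chip marker density
(~280 SNPs/Mb), Hardy–Weinberg background genotypes with SNP-independent
allele frequencies, autozygous tracts planted directly as homozygous
stretches (one allele drawn by frequency), genotyping errors that turn tract
calls heterozygous at a configurable rate (default 0.25%), genome-wide
missingness (default 0.14%), and population-level island regions where a
configurable fraction of individuals carries one shared tract.

Planting homozygous stretches directly, rather than simulating a pedigree or
coalescent, is deliberate: the detector's contracts concern recovering
homozygosity, not demographic realism, and direct planting gives exact
ground truth for every tract boundary, error and missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import MB, classify_roh
from .io import GenotypeDataset, HET, HOM_A1, HOM_A2, MISSING, write_plink, write_population_sidecar


@dataclass(frozen=True)
class IslandSpec:
    """One planted island: a shared autozygous span in part of a population."""

    population: str
    chrom: str
    start_bp: int
    end_bp: int
    carrier_fraction: float
    jitter_bp: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in [0, 1]")
        if self.end_bp <= self.start_bp:
            raise ValueError("island end must exceed start")


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-dataset recipe.  ``seed`` is mandatory.

    Exactly one of ``tracts_per_class`` (per-individual count of random
    tracts per length class) and ``target_froh`` (per-population planted
    autozygous genome fraction) drives random-tract planting; both may be
    ``None`` for island-only datasets.  In fraction mode tract lengths are
    drawn uniformly on ``froh_tract_length_range`` (default 2–16 Mb, the
    length range dominating genomic coverage of autozygosity) and the last
    tract is trimmed so the planted fraction is hit exactly.
    """

    seed: int
    n_chromosomes: int = 2
    chromosome_length_bp: int = 50 * MB
    snp_density_per_mb: float = 280.0
    populations: tuple[tuple[str, int], ...] = (("POP1", 10),)
    tracts_per_class: tuple[tuple[str, int], ...] | None = None
    fixed_tract_lengths_bp: tuple[int, ...] | None = None
    target_froh: tuple[tuple[str, float], ...] | None = None
    froh_tract_length_range: tuple[int, int] = (2 * MB, 16 * MB)
    islands: tuple[IslandSpec, ...] = ()
    het_error_rate: float = 0.0025
    missing_rate: float = 0.0014
    maf_range: tuple[float, float] = (0.05, 0.95)
    class_bounds_mb: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    top_class_max_mb: float = 24.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length_bp < MB:
            raise ValueError("need >= 1 chromosome of >= 1 Mb")
        for r in (self.het_error_rate, self.missing_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")
        modes = sum(x is not None for x in
                    (self.tracts_per_class, self.fixed_tract_lengths_bp, self.target_froh))
        if modes > 1:
            raise ValueError("give only one of tracts_per_class, "
                             "fixed_tract_lengths_bp and target_froh")
        if self.fixed_tract_lengths_bp is not None:
            for ln in self.fixed_tract_lengths_bp:
                if ln >= self.chromosome_length_bp:
                    raise ValueError(f"tract of {ln} bp exceeds chromosome length")
        for spec in self.islands:
            if spec.end_bp > self.chromosome_length_bp:
                raise ValueError(f"island {spec} exceeds chromosome length")

    @property
    def class_length_ranges(self) -> dict[str, tuple[int, int]]:
        b = self.class_bounds_mb
        out = {}
        for i in range(len(b) - 1):
            lab = classify_roh(int(b[i] * MB), b)
            out[lab] = (int(b[i] * MB), int(b[i + 1] * MB))
        lab = classify_roh(int(b[-1] * MB), b)
        out[lab] = (int(b[-1] * MB), int(self.top_class_max_mb * MB))
        return out


@dataclass
class GroundTruth:
    """Everything the generator planted.

    ``tracts``: one row per planted autozygous tract (sample, population,
    chrom, start_bp, end_bp, length_bp, class, source).  ``islands``: one row
    per island spec with realized carrier counts.  ``het_errors`` /
    ``missing``: realized (sample, chrom, pos) of injected calls.
    """

    tracts: pd.DataFrame
    islands: pd.DataFrame
    het_errors: pd.DataFrame
    missing: pd.DataFrame

    def tracts_for(self, sample: str) -> pd.DataFrame:
        return self.tracts[self.tracts["sample"] == sample]


def _draw_positions(rng: np.random.Generator, length_bp: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(n * 1.2)))
    while pos.size < n:
        extra = rng.integers(1, length_bp + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _place_tract(rng: np.random.Generator, length: int, chrom_len: int,
                 occupied: list[tuple[int, int]], max_tries: int = 60):
    """Uniformly place [start, end] of given length avoiding occupied spans."""
    for _ in range(max_tries):
        start = int(rng.integers(1, chrom_len - length + 1))
        end = start + length
        if all(end < s or start > e for (s, e) in occupied):
            return start, end
    return None


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, GroundTruth]:
    """Generate a dataset and its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(cfg.seed)
    chroms = [str(c + 1) for c in range(cfg.n_chromosomes)]
    n_per_chrom = int(round(cfg.snp_density_per_mb * cfg.chromosome_length_bp / MB))

    maps = []
    for c in chroms:
        pos = _draw_positions(rng, cfg.chromosome_length_bp, n_per_chrom)
        maps.append(pd.DataFrame({
            "chrom": c,
            "snp": [f"snp{c}_{i}" for i in range(len(pos))],
            "cm": 0.0,
            "pos": pos.astype(np.int64),
            "a1": "A",
            "a2": "B",
        }))
    snp_map = pd.concat(maps, ignore_index=True)
    m = len(snp_map)
    chrom_cols = {c: np.flatnonzero((snp_map["chrom"] == c).to_numpy()) for c in chroms}
    chrom_pos = {c: snp_map["pos"].to_numpy()[chrom_cols[c]] for c in chroms}

    sample_rows = []
    for pop, size in cfg.populations:
        for i in range(size):
            sample_rows.append(dict(fid=pop, sample=f"{pop}_{i:03d}", father="0",
                                    mother="0", sex="0", phenotype="-9", population=pop))
    samples = pd.DataFrame(sample_rows)
    n = len(samples)

    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    u = rng.random((n, m))
    p_hom1 = freqs ** 2
    p_het = 2 * freqs * (1 - freqs)
    geno = np.full((n, m), HOM_A2, dtype=np.int8)
    geno[u < p_hom1 + p_het] = HET
    geno[u < p_hom1] = HOM_A1

    occupied: dict[int, dict[str, list[tuple[int, int]]]] = {
        i: {c: [] for c in chroms} for i in range(n)
    }
    tract_rows: list[dict] = []
    tract_mask = np.zeros((n, m), dtype=bool)

    def plant(i: int, chrom: str, start: int, end: int, source: str) -> None:
        cols = chrom_cols[chrom]
        pos = chrom_pos[chrom]
        j0 = int(np.searchsorted(pos, start, side="left"))
        j1 = int(np.searchsorted(pos, end, side="right")) - 1
        if j1 >= j0:
            sel = cols[j0:j1 + 1]
            pick = rng.random(sel.size) < freqs[sel]
            geno[i, sel] = np.where(pick, HOM_A1, HOM_A2).astype(np.int8)
            tract_mask[i, sel] = True
        occupied[i][chrom].append((start, end))
        tract_rows.append(dict(sample=samples["sample"].iat[i],
                               population=samples["population"].iat[i],
                               chrom=chrom, start_bp=start, end_bp=end,
                               length_bp=end - start,
                               **{"class": classify_roh(end - start, cfg.class_bounds_mb)},
                               source=source))

    # islands first, so random tracts avoid them
    island_rows = []
    for spec in cfg.islands:
        pop_rows = np.flatnonzero((samples["population"] == spec.population).to_numpy())
        k = int(round(spec.carrier_fraction * pop_rows.size))
        carriers = rng.choice(pop_rows, size=k, replace=False) if k else np.array([], int)
        for i in np.sort(carriers):
            s, e = spec.start_bp, spec.end_bp
            if spec.jitter_bp:
                s = max(1, s + int(rng.integers(-spec.jitter_bp, spec.jitter_bp + 1)))
                e = min(cfg.chromosome_length_bp, e + int(rng.integers(-spec.jitter_bp, spec.jitter_bp + 1)))
            plant(int(i), spec.chrom, s, e, source="island")
        island_rows.append(dict(population=spec.population, chrom=spec.chrom,
                                start_bp=spec.start_bp, end_bp=spec.end_bp,
                                carrier_fraction=spec.carrier_fraction,
                                n_carriers=int(len(carriers))))

    # random tracts: fixed lengths, per-class counts, or a target fraction
    if cfg.fixed_tract_lengths_bp is not None:
        for i in range(n):
            for length in cfg.fixed_tract_lengths_bp:
                for c in rng.permutation(chroms):
                    placed = _place_tract(rng, int(length), cfg.chromosome_length_bp,
                                          occupied[i][c])
                    if placed:
                        plant(i, c, placed[0], placed[1], source="random")
                        break
    elif cfg.tracts_per_class is not None:
        ranges = cfg.class_length_ranges
        for i in range(n):
            for lab, count in cfg.tracts_per_class:
                lo, hi = ranges[lab]
                for _ in range(count):
                    length = int(rng.integers(lo, hi))
                    for c in rng.permutation(chroms):
                        placed = _place_tract(rng, length, cfg.chromosome_length_bp, occupied[i][c])
                        if placed:
                            plant(i, c, placed[0], placed[1], source="random")
                            break
    elif cfg.target_froh is not None:
        genome = cfg.n_chromosomes * cfg.chromosome_length_bp
        targets = dict(cfg.target_froh)
        lo, hi = cfg.froh_tract_length_range
        for i in range(n):
            pop = samples["population"].iat[i]
            if pop not in targets:
                continue
            goal = int(targets[pop] * genome)
            planted = sum(e - s for c in chroms for (s, e) in occupied[i][c])
            while planted < goal:
                length = int(rng.integers(lo, hi))
                length = min(length, goal - planted) if goal - planted >= MB else length
                if goal - planted < MB:
                    break
                for c in rng.permutation(chroms):
                    placed = _place_tract(rng, length, cfg.chromosome_length_bp, occupied[i][c])
                    if placed:
                        plant(i, c, placed[0], placed[1], source="random")
                        planted += length
                        break
                else:
                    break  # genome too crowded to place more

    # genotyping errors: heterozygous calls inside autozygous tracts
    err_mask = tract_mask & (rng.random((n, m)) < cfg.het_error_rate)
    geno[err_mask] = HET
    # missingness: genome-wide
    mis_mask = rng.random((n, m)) < cfg.missing_rate
    geno[mis_mask] = MISSING

    def _positions_frame(mask: np.ndarray) -> pd.DataFrame:
        rows, cols = np.nonzero(mask)
        return pd.DataFrame({
            "sample": samples["sample"].to_numpy()[rows],
            "chrom": snp_map["chrom"].to_numpy()[cols],
            "pos": snp_map["pos"].to_numpy()[cols],
        })

    truth = GroundTruth(
        tracts=pd.DataFrame(tract_rows, columns=["sample", "population", "chrom",
                                                 "start_bp", "end_bp", "length_bp",
                                                 "class", "source"]),
        islands=pd.DataFrame(island_rows, columns=["population", "chrom", "start_bp",
                                                   "end_bp", "carrier_fraction",
                                                   "n_carriers"]),
        het_errors=_positions_frame(err_mask),
        missing=_positions_frame(mis_mask),
    )
    ds = GenotypeDataset(snp_map, samples, geno)
    return ds, truth


def write_fixture(ds: GenotypeDataset, truth: GroundTruth, out_dir,
                  prefix: str = "sim", dialects: tuple[str, ...] = ("ped",)) -> dict[str, Path]:
    """Write the dataset (PLINK dialects), population sidecar and ground
    truth TSVs; everything round-trips through :mod:`rohscan.io`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for d in dialects:
        write_plink(ds, out / prefix, dialect=d)
        paths[d] = out / prefix
    write_population_sidecar(ds, out / f"{prefix}.pop")
    paths["pop"] = out / f"{prefix}.pop"
    truth.tracts.to_csv(out / f"{prefix}.truth_tracts.tsv", sep="\t", index=False)
    truth.islands.to_csv(out / f"{prefix}.truth_islands.tsv", sep="\t", index=False)
    paths["truth_tracts"] = out / f"{prefix}.truth_tracts.tsv"
    paths["truth_islands"] = out / f"{prefix}.truth_islands.tsv"
    return paths


# ---------------------------------------------------------------------------
# ground-truth evaluation
# ---------------------------------------------------------------------------

def evaluate_tract_recovery(truth: GroundTruth, roh, snp_map: pd.DataFrame,
                            min_length_bp: int = 2 * MB,
                            max_boundary_markers: int = 1) -> pd.DataFrame:
    """Score detection of planted tracts against called segments.

    Boundary error is measured inward: how many of the tract's edge markers
    the calls fail to cover.  Outward over-extension into stochastically
    homozygous background is inherent to consecutive-runs detection and does
    not count against recovery.  A tract is ``recovered`` when the union of
    the individual's overlapping called segments misses at most
    ``max_boundary_markers`` markers at each edge; ``single_segment``
    additionally requires one segment to do so alone, and ``class_ok``
    compares that segment's length class with the planted class.  Only
    tracts of at least ``min_length_bp`` are scored.
    """
    seg = roh.segments if hasattr(roh, "segments") else roh
    rows = []
    pos_by_chrom = {c: grp["pos"].to_numpy() for c, grp in snp_map.groupby("chrom", sort=False)}

    def _miss(sample, chrom, start_bp, end_bp, planted):
        return dict(sample=sample, chrom=chrom, start_bp=start_bp, end_bp=end_bp,
                    planted_class=planted, recovered=False, single_segment=False,
                    class_ok=False, start_def_markers=np.nan, end_def_markers=np.nan)

    for _, t in truth.tracts.iterrows():
        if t["length_bp"] < min_length_bp:
            continue
        pos = pos_by_chrom[t["chrom"]]
        j0 = int(np.searchsorted(pos, t["start_bp"], side="left"))
        j1 = int(np.searchsorted(pos, t["end_bp"], side="right")) - 1
        sub = seg[(seg["sample"] == t["sample"]) & (seg["chrom"] == t["chrom"])
                  & (seg["end_bp"] >= t["start_bp"]) & (seg["start_bp"] <= t["end_bp"])]
        if sub.empty or j1 < j0:
            rows.append(_miss(t["sample"], t["chrom"], t["start_bp"], t["end_bp"], t["class"]))
            continue
        u_start = int(np.searchsorted(pos, sub["start_bp"].min()))
        u_end = int(np.searchsorted(pos, sub["end_bp"].max(), side="right")) - 1
        start_def = max(0, u_start - j0)
        end_def = max(0, j1 - u_end)
        single = False
        class_ok = False
        for _, s in sub.iterrows():
            a = int(np.searchsorted(pos, s["start_bp"]))
            b = int(np.searchsorted(pos, s["end_bp"], side="right")) - 1
            if max(0, a - j0) <= max_boundary_markers and max(0, j1 - b) <= max_boundary_markers:
                single = True
                class_ok = s["class"] == t["class"]
                break
        rows.append(dict(sample=t["sample"], chrom=t["chrom"],
                         start_bp=t["start_bp"], end_bp=t["end_bp"],
                         planted_class=t["class"],
                         recovered=(start_def <= max_boundary_markers
                                    and end_def <= max_boundary_markers),
                         single_segment=single, class_ok=class_ok,
                         start_def_markers=start_def, end_def_markers=end_def))
    return pd.DataFrame(rows)
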