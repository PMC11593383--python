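"""Candidate-gene overlap, per-breed summary tables, and the pipeline driver.

Gene annotation is consumed from a local interval table (BED or headered
TSV); no code path performs network access, so results are reproducible from
the files on disk.  Internally coordinates are 1-based inclusive (PLINK map
convention); BED input (0-based half-open) is converted on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import (MB, RohCallConfig, RohSet, calibrate_class_params,
                     first_pass_roh, second_pass_roh)
from .inbreeding import froh_for_dataset, genome_length_from_map, summarize_froh
from .io import (GenotypeDataset, apply_qc, apply_qc_per_population,
                 read_plink, genotyping_rate)
from .islands import IslandConfig, find_islands
from .simulate import IslandSpec, SimConfig, simulate_dataset

logger = logging.getLogger("rohscan")

GENE_COLUMNS = ["chrom", "start_bp", "end_bp", "gene", "source"]


class PipelineStageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""


def read_gene_table(path, fmt: str | None = None, source: str | None = None) -> pd.DataFrame:
    """Read a gene-interval table.

    ``fmt='bed'``: headerless, 0-based half-open (chrom, start, end, name);
    converted to 1-based inclusive by adding 1 to the start.  ``fmt='tsv'``:
    headered chrom/start/end/name columns, already 1-based inclusive.  When
    ``fmt`` is None, ``.bed`` files are treated as BED and everything else as
    TSV.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "tsv"
    src = source or path.name
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene"],
                         dtype={0: str, 3: str})
        out = pd.DataFrame({"chrom": df["chrom"], "start_bp": df["start"].astype(np.int64) + 1,
                            "end_bp": df["end"].astype(np.int64), "gene": df["gene"],
                            "source": src})
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        need = {"chrom", "start", "end", "name"}
        if not need.issubset(df.columns):
            raise ValueError(f"gene TSV needs columns {sorted(need)}")
        out = pd.DataFrame({"chrom": df["chrom"], "start_bp": df["start"].astype(np.int64),
                            "end_bp": df["end"].astype(np.int64), "gene": df["name"],
                            "source": src})
    else:
        raise ValueError(f"unknown gene-table format {fmt!r}")
    if (out["end_bp"] < out["start_bp"]).any():
        raise ValueError("gene interval with end < start")
    return out.reindex(columns=GENE_COLUMNS)


def overlap_genes(islands: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Report every gene whose interval intersects an island interval
    (1-based inclusive coordinates; any >= 1 bp overlap counts).

    Raises a naming error when the two inputs share no chromosome labels.
    """
    if len(islands) and len(genes):
        ic = set(islands["chrom"].astype(str))
        gc = set(genes["chrom"].astype(str))
        if not ic & gc:
            hint = ""
            stripped = {c.removeprefix("chr") for c in gc}
            if ic & stripped:
                hint = " (gene table uses 'chr' prefixes; strip them)"
            raise ValueError(
                f"no shared chromosome names between islands {sorted(ic)[:5]} "
                f"and genes {sorted(gc)[:5]}{hint}")
    rows = []
    for _, isl in islands.iterrows():
        hits = genes[(genes["chrom"].astype(str) == str(isl["chrom"]))
                     & (genes["start_bp"] <= isl["end_bp"])
                     & (genes["end_bp"] >= isl["start_bp"])]
        for _, g in hits.iterrows():
            rows.append(dict(chrom=isl["chrom"], island_start_bp=isl["start_bp"],
                             island_end_bp=isl["end_bp"],
                             population=isl.get("populations", isl.get("population", "")),
                             gene=g["gene"], gene_start_bp=g["start_bp"],
                             gene_end_bp=g["end_bp"]))
    return pd.DataFrame(rows, columns=["chrom", "island_start_bp", "island_end_bp",
                                       "population", "gene", "gene_start_bp",
                                       "gene_end_bp"])


def breed_summary(roh: RohSet | pd.DataFrame, samples: pd.DataFrame,
                  class_labels: list[str] | None = None) -> pd.DataFrame:
    """Per-population ROH statistics.

    ``N_ROH``: total segment count; ``A_ROH``: mean (± sd) segments per
    individual, counting individuals with zero ROH; ``N_SNP``: mean (± sd)
    markers per segment; ``MaxSNP``: largest marker count; ``MeanL_Mb``:
    mean (± sd) length in Mb; ``MaxL_Mb``: largest length; plus one
    ``pct_<class>`` column per length class (percentages sum to 100).
    """
    seg = roh.segments if isinstance(roh, RohSet) else roh
    if class_labels is None:
        class_labels = sorted(seg["class"].unique())
    rows = []
    for pop, pop_samples in samples.groupby("population", sort=False):
        sub = seg[seg["population"] == pop]
        per_ind = sub.groupby("sample").size().reindex(pop_samples["sample"], fill_value=0)
        if sub.empty:
            warnings.warn(f"population {pop!r} has no ROH")
            row = dict(population=pop, N_ROH=0, A_ROH_mean=0.0, A_ROH_sd=0.0,
                       N_SNP_mean=0.0, N_SNP_sd=0.0, MaxSNP=0,
                       MeanL_Mb=0.0, SdL_Mb=0.0, MaxL_Mb=0.0)
            row.update({f"pct_{lab}": 0.0 for lab in class_labels})
        else:
            lens_mb = sub["length_bp"] / MB
            row = dict(population=pop, N_ROH=len(sub),
                       A_ROH_mean=float(per_ind.mean()),
                       A_ROH_sd=float(per_ind.std(ddof=1)) if len(per_ind) > 1 else 0.0,
                       N_SNP_mean=float(sub["n_snp"].mean()),
                       N_SNP_sd=float(sub["n_snp"].std(ddof=1)) if len(sub) > 1 else 0.0,
                       MaxSNP=int(sub["n_snp"].max()),
                       MeanL_Mb=float(lens_mb.mean()),
                       SdL_Mb=float(lens_mb.std(ddof=1)) if len(sub) > 1 else 0.0,
                       MaxL_Mb=float(lens_mb.max()))
            by_class = sub["class"].value_counts()
            for lab in class_labels:
                row[f"pct_{lab}"] = float(by_class.get(lab, 0)) / len(sub) * 100.0
        rows.append(row)
    return pd.DataFrame(rows)


def format_breed_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Human-readable view: Mb statistics to one decimal, mean ± sd merged."""
    out = pd.DataFrame({"Breed": summary["population"], "N_ROH": summary["N_ROH"]})
    out["A_ROH"] = [f"{m:.1f} ± {s:.1f}" for m, s in zip(summary["A_ROH_mean"], summary["A_ROH_sd"])]
    out["N_SNP"] = [f"{m:.1f} ± {s:.1f}" for m, s in zip(summary["N_SNP_mean"], summary["N_SNP_sd"])]
    out["MaxSNP"] = summary["MaxSNP"]
    out["MeanL"] = [f"{m:.1f} ± {s:.1f}" for m, s in zip(summary["MeanL_Mb"], summary["SdL_Mb"])]
    out["MaxL"] = summary["MaxL_Mb"].round(1)
    return out


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (see ``from_yaml``)."""

    output_dir: str
    input_prefix: str | None = None
    input_dialect: str | None = None
    population_file: str | None = None
    simulate: SimConfig | None = None
    qc_max_marker_missing: float = 0.1
    qc_max_sample_missing: float = 0.1
    qc_per_population: bool = False
    roh: RohCallConfig = field(default_factory=RohCallConfig)
    islands: IslandConfig = field(default_factory=IslandConfig)
    gene_table: str | None = None
    gene_table_format: str | None = None
    genome_length_bp: int | None = None

    def __post_init__(self) -> None:
        if (self.input_prefix is None) == (self.simulate is None):
            raise ValueError("exactly one of input_prefix and simulate is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = None
        if "simulate" in raw:
            s = dict(raw["simulate"])
            if "populations" in s:
                s["populations"] = tuple((str(k), int(v)) for k, v in dict(s["populations"]).items())
            if "tracts_per_class" in s and s["tracts_per_class"] is not None:
                s["tracts_per_class"] = tuple((str(k), int(v)) for k, v in dict(s["tracts_per_class"]).items())
            if "target_froh" in s and s["target_froh"] is not None:
                s["target_froh"] = tuple((str(k), float(v)) for k, v in dict(s["target_froh"]).items())
            if "islands" in s:
                s["islands"] = tuple(IslandSpec(**i) for i in s["islands"])
            sim = SimConfig(**s)
        inp = raw.get("input", {})
        qc = raw.get("qc", {})
        roh_cfg = RohCallConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                   for k, v in raw.get("roh", {}).items()})
        isl_cfg = IslandConfig(**raw.get("islands", {}))
        genes = raw.get("genes", {})
        return cls(
            output_dir=raw["output_dir"],
            input_prefix=inp.get("prefix"),
            input_dialect=inp.get("dialect"),
            population_file=inp.get("populations"),
            simulate=sim,
            qc_max_marker_missing=float(qc.get("max_marker_missing", 0.1)),
            qc_max_sample_missing=float(qc.get("max_sample_missing", 0.1)),
            qc_per_population=bool(qc.get("per_population", False)),
            roh=roh_cfg,
            islands=isl_cfg,
            gene_table=genes.get("path"),
            gene_table_format=genes.get("format"),
            genome_length_bp=raw.get("genome_length_bp"),
        )

    def to_canonical_dict(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "input_prefix": self.input_prefix,
            "input_dialect": self.input_dialect,
            "population_file": self.population_file,
            "simulate": asdict(self.simulate) if self.simulate else None,
            "qc": {"max_marker_missing": self.qc_max_marker_missing,
                   "max_sample_missing": self.qc_max_sample_missing,
                   "per_population": self.qc_per_population},
            "roh": asdict(self.roh),
            "islands": asdict(self.islands),
            "gene_table": self.gene_table,
            "genome_length_bp": self.genome_length_bp,
        }
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                logger.info("stage %s", name)
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig | str | Path) -> Path:
    """Run QC → pass 1 → calibration → pass 2 → F_ROH → island scans →
    island calling → sharing → summaries, writing every table plus a
    machine-readable manifest to the configured output directory.

    Outputs are deterministic: rerunning with an identical configuration
    produces byte-identical tables.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("load")
    def load() -> GenotypeDataset:
        if config.simulate is not None:
            ds, truth = simulate_dataset(config.simulate)
            truth.tracts.to_csv(out / "truth_tracts.tsv", sep="\t", index=False)
            truth.islands.to_csv(out / "truth_islands.tsv", sep="\t", index=False)
            return ds
        return read_plink(config.input_prefix, dialect=config.input_dialect,
                          population_file=config.population_file)

    ds = load()

    @_stage("qc")
    def qc(ds):
        fn = apply_qc_per_population if config.qc_per_population else apply_qc
        ds2, rep = fn(ds, config.qc_max_marker_missing, config.qc_max_sample_missing)
        rep.write_tsv(out / "qc_report.tsv")
        return ds2, rep

    ds, qc_report = qc(ds)

    @_stage("roh")
    def roh(ds):
        p1 = first_pass_roh(ds, config.roh)
        params = calibrate_class_params(p1, config.roh)
        p2 = second_pass_roh(ds, params, config.roh)
        p1.write_tsv(out / "roh_pass1.tsv")
        params.write_tsv(out / "class_params.tsv")
        p2.write_tsv(out / "roh.tsv")
        return p1, params, p2

    pass1, params, pass2 = roh(ds)

    @_stage("froh")
    def froh(ds, pass2):
        rec = froh_for_dataset(ds, pass2, genome_length_bp=config.genome_length_bp,
                               by_class=True)
        rec.to_csv(out / "froh.tsv", sep="\t", index=False)
        summ = summarize_froh(rec)
        summ.to_csv(out / "froh_summary.tsv", sep="\t", index=False)
        return rec, summ

    froh_records, froh_summary = froh(ds, pass2)

    @_stage("islands")
    def islands(ds, pass2):
        scans, isl, regions, memberships = find_islands(ds, pass2, config.islands)
        for pop, scan in scans.items():
            scan.write_tsv(out / f"incidence_{pop}.tsv")
        isl.to_csv(out / "islands.tsv", sep="\t", index=False)
        regions.to_csv(out / "shared_islands.tsv", sep="\t", index=False)
        memberships.to_csv(out / "island_memberships.tsv", sep="\t", index=False)
        thresholds = pd.DataFrame(
            [{"population": p, "population_size": s.population_size,
              "mean_pct": s.mean_pct, "sd_pct": s.sd_pct,
              "z_critical": s.z_critical, "threshold_pct": s.threshold_pct}
             for p, s in scans.items()])
        thresholds.to_csv(out / "island_thresholds.tsv", sep="\t", index=False)
        return scans, isl, regions, memberships

    scans, isl, regions, memberships = islands(ds, pass2)

    @_stage("report")
    def report(ds, pass2, regions):
        summ = breed_summary(pass2, ds.samples, class_labels=config.roh.class_labels)
        summ.to_csv(out / "breed_summary.tsv", sep="\t", index=False)
        format_breed_summary(summ).to_csv(out / "breed_summary_formatted.tsv",
                                          sep="\t", index=False)
        if config.gene_table:
            genes = read_gene_table(config.gene_table, config.gene_table_format)
            ov = overlap_genes(regions, genes)
            ov.to_csv(out / "island_genes.tsv", sep="\t", index=False)
        return summ

    report(ds, pass2, regions)

    @_stage("manifest")
    def manifest():
        cfg_dict = config.to_canonical_dict()
        cfg_blob = json.dumps(cfg_dict, sort_keys=True, default=str)
        man = {
            "rohscan_version": __version__,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
            "n_samples": int(ds.n_samples),
            "n_markers": int(ds.n_markers),
            "genotyping_rate": genotyping_rate(ds),
            "genome_length_bp": int(config.genome_length_bp
                                    or genome_length_from_map(ds.snp_map)),
            "n_roh_pass1": len(pass1),
            "n_roh": len(pass2),
            "n_islands": int(len(isl)),
            "n_shared_regions": int(len(regions)),
            "resolved_parameters": {
                "qc": cfg_dict["qc"], "roh": cfg_dict["roh"], "islands": cfg_dict["islands"],
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(man, fh, indent=2, sort_keys=True, default=str)

    manifest()
    return out
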