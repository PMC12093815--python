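"""End-to-end orchestration: fragments -> dyad tracks -> nucleosome calls ->
+1 shifts -> NRL statistics -> composite profiles.

The pipeline is driven by a single declarative YAML config (see
:func:`validate_config`); every stochastic stage derives its seed from the
global seed, so a rerun with the same config reproduces identical outputs.
All parameter defaults are the analysis constants of the protocol:
mono-nucleosome size selection 140-160 bp, dyad extension +-50 bp,
subsampling to 5 million fragments, and the 10 bp all-replicates shift rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (read_chrom_sizes, read_genes, write_chrom_sizes,
                         write_genes_bed, write_genes_gff3)
from .calling import (CallerParams, call_nucleosomes, dyad_count_arrays,
                      write_calls)
from .composite import (DEFAULT_WINDOW as COMPOSITE_WINDOW, CompositeProfile,
                        composite, peak_shift, plot_profiles, write_profiles)
from .fragments import (exclude_regions, filter_by_length, read_fragments,
                        read_regions_bed, subsample)
from .nrl import nrl_table, set_nrl, welch_t, write_nrl_table
from .shifts import (DEFAULT_WINDOW as SHIFT_WINDOW, dependent_genes,
                     shift_table, write_shift_table)
from .simulate import (SimConfig, sample_seed, simulate_experiment,
                       write_fragments_bed, write_truth)
from .tracks import build_dyad_track, write_track

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with one message per violated config field."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid config:\n  " + "\n  ".join(problems))


@dataclass(frozen=True)
class FilterParams:
    min_len: int = 140
    max_len: int = 160
    exclude: tuple = ()          # (chrom, start, end) triples
    subsample_n: int = 5_000_000
    extension_radius: int = 50


@dataclass(frozen=True)
class ShiftParams:
    wt_condition: str = "wt"
    mut_condition: str = "mut"
    threshold: float = 10.0
    window: tuple[int, int] = SHIFT_WINDOW


@dataclass(frozen=True)
class NRLParams:
    min_nucs: int = 4
    max_nucs: int = 8


@dataclass(frozen=True)
class CompositeParams:
    window: tuple[int, int] = COMPOSITE_WINDOW
    anchor_mode: str = "tss"
    normalization: str = "none"
    peak_window: tuple[int, int] = (0, 200)  # the +1 peak region


@dataclass(frozen=True)
class SampleSpec:
    name: str
    condition: str
    replicate: int
    fragments: str


@dataclass
class RunConfig:
    output_dir: Path
    seed: int = 7
    samples: list[SampleSpec] = field(default_factory=list)
    genes_path: str | None = None
    chrom_sizes_path: str | None = None
    simulate: SimConfig | None = None
    sim_conditions: tuple[str, ...] = ("wt", "mut")
    sim_replicates: int = 2
    filters: FilterParams = field(default_factory=FilterParams)
    caller: CallerParams = field(default_factory=CallerParams)
    shifts: ShiftParams = field(default_factory=ShiftParams)
    nrl: NRLParams = field(default_factory=NRLParams)
    composite: CompositeParams = field(default_factory=CompositeParams)


def _build(section: dict, cls, path: str, problems: list[str], **extra):
    known = {f for f in cls.__dataclass_fields__}
    bad = set(section) - known
    for key in sorted(bad):
        problems.append(f"{path}.{key}: unknown field")
    kwargs = {k: v for k, v in section.items() if k in known}
    for key in ("window", "peak_window", "frag_len_bounds"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    try:
        return cls(**kwargs, **extra)
    except (TypeError, ValueError) as exc:
        problems.append(f"{path}: {exc}")
        return None


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; raise ConfigError on violations.

    Defaults (140/160 bp size selection, 50 bp extension, 5M subsample,
    10 bp threshold) are filled in and echoed in the returned object.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ConfigError([f"unparseable YAML{line}: {exc}"])
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])

    problems: list[str] = []
    out_dir = raw.get("output_dir")
    if not out_dir:
        problems.append("output_dir: required")
    seed = raw.get("seed", 7)
    if not isinstance(seed, int):
        problems.append(f"seed: must be an integer, got {seed!r}")
        seed = 7

    filters = _build(raw.get("filters", {}), FilterParams, "filters", problems)
    caller = _build(raw.get("caller", {}), CallerParams, "caller", problems)
    shifts_p = _build(raw.get("shifts", {}), ShiftParams, "shifts", problems)
    nrl_p = _build(raw.get("nrl", {}), NRLParams, "nrl", problems)
    comp_p = _build(raw.get("composite", {}), CompositeParams, "composite", problems)

    sim = None
    if "simulate" in raw:
        section = dict(raw["simulate"])
        sim_reps = section.pop("replicates", 2)
        sim_conds = tuple(section.pop("conditions", ("wt", "mut")))
        section.setdefault("seed", seed)
        if "effect_genes" in section:
            section["effect_genes"] = frozenset(section["effect_genes"])
        sim = _build(section, SimConfig, "simulate", problems)
    else:
        sim_reps, sim_conds = 2, ("wt", "mut")

    samples = []
    names_seen: dict[str, int] = {}
    for i, entry in enumerate(raw.get("samples", [])):
        spec = _build(entry, SampleSpec, f"samples[{i}]", problems)
        if spec is None:
            continue
        if spec.name in names_seen:
            problems.append(
                f"samples[{i}].name: duplicate sample name {spec.name!r} "
                f"(also row {names_seen[spec.name]})")
        names_seen[spec.name] = i
        if not Path(spec.fragments).exists():
            problems.append(f"samples[{i}].fragments: path not found: {spec.fragments}")
        samples.append(spec)
    if sim is None and not samples:
        problems.append("samples: required unless a simulate section is given")

    genes_path = raw.get("genes")
    sizes_path = raw.get("chrom_sizes")
    for label, p in (("genes", genes_path), ("chrom_sizes", sizes_path)):
        if p is not None and not Path(p).exists():
            problems.append(f"{label}: path not found: {p}")
    if sim is None:
        if genes_path is None:
            problems.append("genes: required unless simulating")
        if sizes_path is None:
            problems.append("chrom_sizes: required unless simulating")

    exclude_path = raw.get("filters", {}).get("exclude") if isinstance(
        raw.get("filters"), dict) else None
    if isinstance(exclude_path, str):
        if not Path(exclude_path).exists():
            problems.append(f"filters.exclude: path not found: {exclude_path}")
        elif filters is not None:
            filters = FilterParams(**{**asdict(filters),
                                      "exclude": tuple(read_regions_bed(exclude_path))})

    if problems:
        raise ConfigError(problems)
    return RunConfig(output_dir=Path(out_dir), seed=seed, samples=samples,
                     genes_path=genes_path, chrom_sizes_path=sizes_path,
                     simulate=sim, sim_conditions=sim_conds,
                     sim_replicates=sim_reps, filters=filters, caller=caller,
                     shifts=shifts_p, nrl=nrl_p, composite=comp_p)


# ---------------------------------------------------------------------------
# in-memory analysis (used by run_pipeline, the tests, and the acceptance
# script; no file IO)


def process_sample(frags: pd.DataFrame, chrom_sizes: dict[str, int],
                   filters: FilterParams, caller: CallerParams,
                   seed: int) -> dict:
    """Filter -> exclude -> subsample -> dyad track -> nucleosome calls."""
    stats = {"fragments_in": len(frags)}
    frags = filter_by_length(frags, filters.min_len, filters.max_len)
    stats["after_length_filter"] = len(frags)
    frags = exclude_regions(frags, list(filters.exclude))
    stats["after_exclusion"] = len(frags)
    frags = subsample(frags, filters.subsample_n, seed=seed)
    stats["after_subsample"] = len(frags)
    track = build_dyad_track(frags, chrom_sizes, filters.extension_radius,
                             provenance={"filters": asdict(filters), "seed": seed})
    raw = dyad_count_arrays(frags, chrom_sizes)
    calls = call_nucleosomes(track, caller, raw=raw)
    stats["n_calls"] = len(calls)
    return {"track": track, "calls": calls, "stats": stats}


def analyze_experiment(samples: dict[tuple[str, int], pd.DataFrame],
                       chrom_sizes: dict[str, int], genes: pd.DataFrame,
                       filters: FilterParams = FilterParams(),
                       caller: CallerParams = CallerParams(),
                       shift_params: ShiftParams = ShiftParams(),
                       nrl_params: NRLParams = NRLParams(),
                       comp_params: CompositeParams = CompositeParams(),
                       seed: int = 7) -> dict:
    """Run the full analysis on in-memory per-sample fragment tables.

    ``samples`` maps (condition, replicate) -> fragment DataFrame.  Returns
    processed samples, the shift table, dependent genes, per-sample NRL
    tables and summaries, Welch results, and per-condition composites.
    """
    processed = {}
    for i, (key, frags) in enumerate(sorted(samples.items())):
        processed[key] = process_sample(frags, chrom_sizes, filters, caller,
                                        seed=sample_seed(seed, 900 + i, 0))
    calls_by_sample = {k: v["calls"] for k, v in processed.items()}

    shifts_df = shift_table(calls_by_sample, genes,
                            wt_condition=shift_params.wt_condition,
                            mut_condition=shift_params.mut_condition,
                            threshold=shift_params.threshold,
                            window=shift_params.window)
    dep_genes = dependent_genes(shifts_df, genes)

    nrl_by_sample = {k: nrl_table(v["calls"], genes,
                                  window=shift_params.window,
                                  min_nucs=nrl_params.min_nucs,
                                  max_nucs=nrl_params.max_nucs)
                     for k, v in processed.items()}

    gene_sets = {"all": genes}
    if len(dep_genes):
        gene_sets["dependent"] = dep_genes
    summaries = []
    mean_by_cond: dict[str, dict[str, list[float]]] = {}
    for set_label, gset in gene_sets.items():
        ids = set(gset["gene_id"])
        for (condition, rep), tab in nrl_by_sample.items():
            vals = tab.loc[tab["gene_id"].isin(ids), "nrl"]
            if len(vals) == 0:
                continue
            s = set_nrl(vals, f"{set_label}/{condition}_rep{rep}")
            s.update({"set": set_label, "condition": condition, "replicate": rep})
            summaries.append(s)
            mean_by_cond.setdefault(set_label, {}).setdefault(
                condition, []).append(s["mean"])
    summary_df = pd.DataFrame(summaries)

    welch = {}
    for set_label, by_cond in mean_by_cond.items():
        a = by_cond.get(shift_params.wt_condition, [])
        b = by_cond.get(shift_params.mut_condition, [])
        try:
            welch[set_label] = welch_t(a, b)
        except ValueError as exc:
            welch[set_label] = str(exc)

    composites: dict[str, dict[str, CompositeProfile]] = {}
    for set_label, gset in gene_sets.items():
        per_cond: dict[str, CompositeProfile] = {}
        for condition in {c for c, _ in processed}:
            reps = [v for (c, _), v in sorted(processed.items()) if c == condition]
            profs = [composite(v["track"], gset, window=comp_params.window,
                               anchor_mode="tss",
                               normalization=comp_params.normalization)
                     for v in reps]
            per_cond[condition] = CompositeProfile(
                window=comp_params.window,
                values=np.mean([p.values for p in profs], axis=0),
                n_genes=profs[0].n_genes, n_dropped=profs[0].n_dropped,
                anchor_mode="tss", normalization=comp_params.normalization)
        composites[set_label] = per_cond

    peak_shifts = {}
    for set_label, per_cond in composites.items():
        a = per_cond.get(shift_params.wt_condition)
        b = per_cond.get(shift_params.mut_condition)
        if a is not None and b is not None:
            peak_shifts[set_label] = peak_shift(a, b, comp_params.peak_window)

    return {"samples": processed, "shift_table": shifts_df,
            "dependent_genes": dep_genes, "nrl_by_sample": nrl_by_sample,
            "nrl_summary": summary_df, "welch": welch,
            "composites": composites, "peak_shifts": peak_shifts}


# ---------------------------------------------------------------------------
# file-level run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing outputs + manifest under output_dir.

    Returns the report dict (also written as report.json).  On stage
    failure a FAILED marker naming the stage is left in the output
    directory and the error is re-raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("nucorg")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stage = "setup"
    outputs: list[Path] = []
    t_start = time.time()
    try:
        if config.simulate is not None:
            stage = "simulate"
            t0 = time.time()
            sim_dir = out / "sim"
            sim_dir.mkdir(exist_ok=True)
            exp = simulate_experiment(config.simulate,
                                      conditions=config.sim_conditions,
                                      n_replicates=config.sim_replicates)
            chrom_sizes, genes = exp["chrom_sizes"], exp["genes"]
            write_chrom_sizes(chrom_sizes, sim_dir / "chrom.sizes")
            write_genes_gff3(genes, sim_dir / "genes.gff3")
            write_genes_bed(genes, sim_dir / "genes.bed")
            write_truth(exp["truth"], sim_dir / "truth.tsv")
            samples = {}
            for (cond, rep), frags in exp["samples"].items():
                bed = sim_dir / f"{cond}_rep{rep}.bed"
                write_fragments_bed(frags, bed)
                outputs.append(bed)
                samples[(cond, rep)] = frags
            outputs += [sim_dir / "chrom.sizes", sim_dir / "genes.gff3",
                        sim_dir / "genes.bed", sim_dir / "truth.tsv"]
            logger.info("simulate: %d samples in %.1fs", len(samples),
                        time.time() - t0)
        else:
            stage = "load-inputs"
            chrom_sizes = read_chrom_sizes(config.chrom_sizes_path)
            genes = read_genes(config.genes_path)
            samples = {}
            for spec in config.samples:
                frags = read_fragments(spec.fragments)
                samples[(spec.condition, spec.replicate)] = frags
                logger.info("loaded %s: %d fragments", spec.name, len(frags))

        stage = "analysis"
        results = analyze_experiment(
            samples, chrom_sizes, genes, filters=config.filters,
            caller=config.caller, shift_params=config.shifts,
            nrl_params=config.nrl, comp_params=config.composite,
            seed=config.seed)
        for key, proc in results["samples"].items():
            logger.info("sample %s: %s", key, proc["stats"])

        stage = "write-outputs"
        (out / "tracks").mkdir(exist_ok=True)
        (out / "calls").mkdir(exist_ok=True)
        (out / "nrl").mkdir(exist_ok=True)
        for (cond, rep), proc in results["samples"].items():
            name = f"{cond}_rep{rep}"
            tpath = out / "tracks" / f"{name}.bedgraph"
            write_track(proc["track"], tpath)
            cpath = out / "calls" / f"{name}.tsv"
            write_calls(proc["calls"], cpath)
            outputs += [tpath, cpath]
        write_shift_table(results["shift_table"], out / "shifts.tsv")
        outputs.append(out / "shifts.tsv")
        write_genes_bed(results["dependent_genes"], out / "dependent_genes.bed")
        outputs.append(out / "dependent_genes.bed")
        for (cond, rep), tab in results["nrl_by_sample"].items():
            npath = out / "nrl" / f"{cond}_rep{rep}.tsv"
            write_nrl_table(tab, npath)
            outputs.append(npath)
        if len(results["nrl_summary"]):
            results["nrl_summary"].to_csv(out / "nrl_summary.tsv", sep="\t",
                                          index=False, float_format="%.4f")
            outputs.append(out / "nrl_summary.tsv")
        for set_label, per_cond in results["composites"].items():
            ppath = out / f"composite_{set_label}.tsv"
            write_profiles(per_cond, ppath)
            outputs.append(ppath)
            plot_profiles(per_cond, out / f"composite_{set_label}.png",
                          title=f"{set_label} genes")

        stage = "report"
        dep = results["shift_table"]["dependent"]
        report = {
            "version": __version__,
            "seed": config.seed,
            "n_genes": int(len(genes)),
            "n_samples": len(results["samples"]),
            "n_dependent": int(dep.fillna(False).astype(bool).sum()),
            "n_unclassified": int(dep.isna().sum()),
            "peak_shifts_bp": {k: int(v) for k, v in results["peak_shifts"].items()},
            "welch": {k: (asdict(v) if not isinstance(v, str) else v)
                      for k, v in results["welch"].items()},
            "sample_stats": {f"{c}_rep{r}": p["stats"]
                             for (c, r), p in results["samples"].items()},
        }
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True) + "\n")
        outputs.append(out / "report.json")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "filters": {**asdict(config.filters),
                            "exclude": [list(r) for r in config.filters.exclude]},
                "caller": asdict(config.caller),
                "shifts": asdict(config.shifts),
                "nrl": asdict(config.nrl),
                "composite": asdict(config.composite),
            },
            "outputs": {str(p.relative_to(out)): _sha256(p)
                        for p in sorted(set(outputs))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
        logger.info("pipeline finished in %.1fs", time.time() - t_start)
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
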