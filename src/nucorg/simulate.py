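"""Synthetic paired-end MNase-Seq data with known nucleosome positions.

The generator emulates the statistical structure a nucleosome-organization
analysis assumes in budding yeast: each gene carries a positioned +1
nucleosome a fixed offset downstream of its TSS, followed by a phased array
with a configurable nucleosome repeat length (NRL, ~165 bp).  Observed dyads
scatter around the true positions with Gaussian fuzziness, fragment lengths
follow a truncated normal law centered at the mono-nucleosome size, and a
configurable fraction of fragments is uniform background.  Condition effects
(a downstream +1 shift at a subset of genes, an NRL change) model the loss of
a chromatin remodeler at its target genes.

Everything is seeded and deterministic: the same config produces
byte-identical output files, and a ground-truth sidecar lets tests join
nucleosome calls back to the true dyad positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GENE_COLUMNS, validate_genes

#: margin kept free at both chromosome ends so fragments never need clipping
EDGE_MARGIN = 1000
#: slack added beyond the last true dyad when drawing gene-body ends
BODY_PAD = 150

TRUTH_COLUMNS = ["gene_id", "condition", "k", "dyad_pos", "strand", "chrom"]


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated MNase-Seq experiment.

    Defaults describe one condition of the reference design used throughout
    the test-suite: 200 genes on a 1 Mb chromosome, NRL 165 bp, +1 dyad 60 bp
    downstream of the TSS, 20 bp positional fuzziness, fragment lengths
    N(151, 6) truncated to [120, 200], 5% uniform background, and a depth
    giving ~300 signal fragments per nucleosome.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    n_genes: int = 200
    gene_spacing: int = 4000
    plus1_offset: int = 60
    nrl: int = 165
    n_nucs_per_gene: int = 8
    fuzziness_sd: float = 20.0
    frag_len_mean: float = 151.0
    frag_len_sd: float = 6.0
    frag_len_bounds: tuple[int, int] = (120, 200)
    depth: int = 505_263
    background_frac: float = 0.05
    effect_genes: frozenset[str] = field(default_factory=frozenset)
    plus1_shift: int = 0
    nrl_delta: int = 0

    def __post_init__(self):
        object.__setattr__(self, "effect_genes", frozenset(self.effect_genes))
        problems = []
        lo, hi = self.frag_len_bounds
        if not (lo <= self.frag_len_mean <= hi):
            problems.append(
                f"frag_len_mean={self.frag_len_mean} outside frag_len_bounds={self.frag_len_bounds}")
        if not (0 <= self.background_frac < 1):
            problems.append(f"background_frac={self.background_frac} not in [0, 1)")
        if self.nrl <= 0:
            problems.append(f"nrl={self.nrl} must be positive")
        if self.nrl + self.nrl_delta <= 0:
            problems.append(f"nrl + nrl_delta = {self.nrl + self.nrl_delta} must be positive")
        for name in ("n_chroms", "chrom_length", "gene_spacing", "n_nucs_per_gene"):
            if getattr(self, name) <= 0:
                problems.append(f"{name}={getattr(self, name)} must be positive")
        if self.n_genes < 0 or self.depth < 0:
            problems.append("n_genes and depth must be non-negative")
        if self.fuzziness_sd < 0 or self.frag_len_sd < 0:
            problems.append("fuzziness_sd and frag_len_sd must be non-negative")
        if problems:
            raise SimConfigError("; ".join(problems))

    @property
    def array_span(self) -> int:
        """Distance from TSS to the end of the gene body used in annotation."""
        return self.plus1_offset + (self.n_nucs_per_gene - 1) * self.nrl + BODY_PAD


def chrom_name(i: int) -> str:
    return f"chrS{i + 1:02d}"


def build_toy_genome(config: SimConfig) -> tuple[dict[str, int], pd.DataFrame]:
    """Lay out ``n_genes`` gene models with alternating strands.

    Genes are placed on regularly spaced slots, filling chromosomes in order.
    Returns (chrom_sizes, gene table).  Deterministic: the layout depends
    only on the config.
    """
    sizes = {chrom_name(i): config.chrom_length for i in range(config.n_chroms)}
    if config.n_genes == 0:
        return sizes, pd.DataFrame(columns=GENE_COLUMNS)
    per_chrom = math.ceil(config.n_genes / config.n_chroms)
    span = config.array_span
    rows = []
    for i in range(config.n_genes):
        chrom = chrom_name(i // per_chrom)
        slot = i % per_chrom
        slot_start = EDGE_MARGIN + slot * config.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss, body_end = slot_start, slot_start + span
        else:
            tss, body_end = slot_start + span, slot_start
        hi = max(tss, body_end)
        if hi + EDGE_MARGIN > config.chrom_length:
            raise SimConfigError(
                f"gene_{i:04d} does not fit: needs {hi + EDGE_MARGIN} bp on {chrom} "
                f"of length {config.chrom_length} "
                f"(n_genes={config.n_genes}, gene_spacing={config.gene_spacing}, "
                f"n_chroms={config.n_chroms})")
        rows.append((f"gene_{i:04d}", chrom, tss, strand, body_end))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return sizes, validate_genes(genes)


def place_arrays(genes: pd.DataFrame, config: SimConfig,
                 conditions: Sequence[str] = ("wt", "mut")) -> pd.DataFrame:
    """True dyad positions per gene and condition.

    In the first (reference) condition every gene is unperturbed.  In every
    other condition, genes in ``config.effect_genes`` have all dyads
    displaced downstream by ``plus1_shift`` and are re-phased with
    ``nrl + nrl_delta``; other genes are unchanged.  Minus-strand arrays are
    the mirror image about the TSS (shifts act along the transcript).
    """
    if genes.empty:
        raise SimConfigError("place_arrays requires a non-empty annotation")
    ks = np.arange(config.n_nucs_per_gene)
    out = []
    for ci, condition in enumerate(conditions):
        for row in genes.itertuples(index=False):
            affected = ci > 0 and row.gene_id in config.effect_genes
            shift = config.plus1_shift if affected else 0
            nrl = config.nrl + (config.nrl_delta if affected else 0)
            offsets = config.plus1_offset + shift + ks * nrl
            sign = 1 if row.strand == "+" else -1
            dyads = row.tss + sign * offsets
            if dyads.min() < 0 or dyads.max() >= config.chrom_length:
                raise SimConfigError(
                    f"nucleosome array of {row.gene_id} ({condition}) exceeds "
                    f"chromosome bounds [0, {config.chrom_length})")
            for k, dyad in zip(ks, dyads):
                out.append((row.gene_id, condition, int(k), int(dyad),
                            row.strand, row.chrom))
    return pd.DataFrame(out, columns=TRUTH_COLUMNS)


def _draw_lengths(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Rounded-normal fragment lengths with rejection outside the bounds."""
    lo, hi = config.frag_len_bounds
    if config.frag_len_sd == 0:
        return np.full(n, int(round(config.frag_len_mean)), dtype=np.int64)
    lengths = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    while todo.size:
        draw = np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd,
                                  todo.size)).astype(np.int64)
        ok = (draw >= lo) & (draw <= hi)
        lengths[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return lengths


def sample_fragments(truth: pd.DataFrame, config: SimConfig,
                     condition: str | None = None,
                     seed=None) -> pd.DataFrame:
    """Draw ``config.depth`` paired-end fragments for one condition.

    Signal fragments pick a (gene, nucleosome) uniformly from the truth
    table, scatter the observed dyad N(true, fuzziness_sd), and draw a
    truncated-normal length; the emitted interval is
    ``[dyad - len//2, dyad - len//2 + len)``.  Background fragments are
    uniform over the genome with the same length law.  Exactly ``depth``
    fragments are returned (``round(depth * background_frac)`` of them
    background).
    """
    if condition is None:
        conds = truth["condition"].unique()
        if len(conds) != 1:
            raise ValueError(
                f"truth table has conditions {list(conds)}; pass condition=")
        condition = conds[0]
    rows = truth[truth["condition"] == condition]
    if rows.empty and config.depth > 0 and config.background_frac < 1:
        raise ValueError(f"no truth rows for condition {condition!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_bg = int(round(config.depth * config.background_frac))
    n_sig = config.depth - n_bg

    pick = rng.integers(0, len(rows), n_sig) if n_sig else np.empty(0, dtype=int)
    true_dyads = rows["dyad_pos"].to_numpy()[pick]
    chroms_sig = rows["chrom"].to_numpy()[pick]
    if config.fuzziness_sd > 0:
        dyads = np.rint(true_dyads + rng.normal(0, config.fuzziness_sd, n_sig)
                        ).astype(np.int64)
    else:
        dyads = true_dyads.astype(np.int64)
    lens_sig = _draw_lengths(rng, n_sig, config)
    starts_sig = dyads - lens_sig // 2
    ends_sig = starts_sig + lens_sig

    chrom_names = [chrom_name(i) for i in range(config.n_chroms)]
    lens_bg = _draw_lengths(rng, n_bg, config)
    ci = rng.integers(0, config.n_chroms, n_bg)
    starts_bg = rng.integers(0, config.chrom_length - lens_bg + 1)
    ends_bg = starts_bg + lens_bg
    chroms_bg = np.array(chrom_names, dtype=object)[ci]

    frags = pd.DataFrame({
        "chrom": np.concatenate([chroms_sig, chroms_bg]),
        "start": np.concatenate([starts_sig, starts_bg]).astype(np.int64),
        "end": np.concatenate([ends_sig, ends_bg]).astype(np.int64),
    })
    frags = frags.sort_values(["chrom", "start", "end"], kind="stable",
                              ignore_index=True)
    return frags


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    """6-column BED (chrom, start, end, name, score=0, strand='.')."""
    bed = pd.DataFrame({
        "chrom": frags["chrom"], "start": frags["start"], "end": frags["end"],
        "name": [f"frag_{i:07d}" for i in range(len(frags))],
        "score": 0, "strand": ".",
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition": str,
                                              "strand": str, "chrom": str})


def sample_seed(base_seed: int, condition_index: int, replicate: int) -> int:
    """Stable per-sample seed below 2**31 derived from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), int(condition_index), int(replicate)])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def simulate_experiment(config: SimConfig,
                        conditions: Sequence[str] = ("wt", "mut"),
                        n_replicates: int = 2,
                        ) -> dict:
    """Generate genome, truth, and per-sample fragment tables.

    Returns a dict with keys ``chrom_sizes``, ``genes``, ``truth`` and
    ``samples`` (mapping ``(condition, replicate)`` -> fragment DataFrame).
    Replicates share the truth but use independent derived seeds.
    """
    sizes, genes = build_toy_genome(config)
    truth = place_arrays(genes, config, conditions=conditions)
    samples = {}
    for ci, condition in enumerate(conditions):
        for rep in range(1, n_replicates + 1):
            seed = sample_seed(config.seed, ci, rep)
            samples[(condition, rep)] = sample_fragments(
                truth, config, condition=condition, seed=seed)
    return {"chrom_sizes": sizes, "genes": genes, "truth": truth,
            "samples": samples}
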