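"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is seed-deterministic and returns its ground truth
(planted regulons, signature genes, motif positions, position classes)
beside the data, so each downstream stage can be tested plant-and-
recover style.

The expression model is linear-Gaussian on the log2 scale: candidate
regulator (TF) profiles are independent normals; each target gene
follows a single planted TF through a regression weight plus noise;
differentiation adds a fixed log2 effect to the signature genes — the
union of the regulons of a few planted master-regulator TFs — in every
cell line, so the per-line signatures intersect by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DIFF,
    UNDIFF,
    CtTable,
    ExpressionMatrix,
    GenomicInterval,
    PWM,
)

# ---------------------------------------------------------------------------
# expression dataset
# ---------------------------------------------------------------------------


@dataclass
class PlantedModel:
    """Ground-truth generative model for the expression dataset.

    Defaults are the desk-scale study conditions: 20 candidate TFs,
    200 target genes, 100 samples per condition per cell line, a log2
    effect of 2.0 (fourfold) on signature genes and log2 noise SD 0.5.
    """

    n_tfs: int = 20
    n_genes: int = 200
    samples_per_condition: int = 100
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 1
    n_master_regulators: int = 5
    regulon_size_range: tuple[int, int] = (5, 30)
    weight_range: tuple[float, float] = (0.6, 1.0)
    baseline: float = 8.0
    two_probe_fraction: float = 0.2
    # ground truth, filled by plant_structure()
    regulon_map: dict[str, set[str]] = field(default_factory=dict)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    master_tfs: list[str] = field(default_factory=list)
    signature_genes: set[str] = field(default_factory=set)
    probe_map: dict[str, str] = field(default_factory=dict)

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:03d}" for i in range(self.n_tfs)]

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def planted_edges(self) -> set[tuple[str, str]]:
        return set(self.weights)


def plant_structure(model: PlantedModel) -> PlantedModel:
    """Fill in regulons, weights, master TFs, signature and probe map."""
    rng = np.random.default_rng(model.seed)
    tfs, genes = model.tf_names, model.gene_names
    lo, hi = model.regulon_size_range
    if model.n_genes < model.n_tfs * lo:
        raise ValueError("too few genes for the minimum regulon size")
    sizes = np.full(model.n_tfs, lo)
    for _ in range(model.n_genes - sizes.sum()):
        open_tfs = np.flatnonzero(sizes < hi)
        sizes[rng.choice(open_tfs)] += 1
    order = rng.permutation(model.n_genes)
    regulon_map: dict[str, set[str]] = {}
    weights: dict[tuple[str, str], float] = {}
    cursor = 0
    for tf, size in zip(tfs, sizes):
        members = {genes[i] for i in order[cursor : cursor + size]}
        cursor += size
        regulon_map[tf] = members
        for gene in sorted(members):
            w = rng.uniform(*model.weight_range) * rng.choice([-1.0, 1.0])
            weights[(tf, gene)] = float(w)
    n_master = min(model.n_master_regulators, model.n_tfs)
    masters = sorted(str(t) for t in rng.choice(tfs, size=n_master, replace=False))
    signature = set().union(*(regulon_map[tf] for tf in masters))
    probe_map: dict[str, str] = {}
    all_genes = tfs + genes
    doubled = set(
        rng.choice(
            all_genes,
            size=int(round(model.two_probe_fraction * len(all_genes))),
            replace=False,
        )
    )
    for g in all_genes:
        probe_map[f"{g}_p1"] = g
        if g in doubled:
            probe_map[f"{g}_p2"] = g
    return replace(
        model,
        regulon_map=regulon_map,
        weights=weights,
        master_tfs=list(masters),
        signature_genes=signature,
        probe_map=probe_map,
    )


def generate_expression_dataset(
    model: PlantedModel, n_cell_lines: int = 3
) -> tuple[list[ExpressionMatrix], PlantedModel]:
    """Simulate probe-level matrices for ``n_cell_lines`` cell lines.

    Probe-level values add a small replicate noise (0.2 x noise_sd) so
    multi-probe genes exercise probe collapsing; the noiseless limit
    therefore stays exactly noiseless.
    """
    if n_cell_lines < 1:
        raise ValueError("need at least one cell line")
    if model.samples_per_condition < 2:
        raise ValueError("need at least two samples per condition")
    if not model.regulon_map:
        model = plant_structure(model)
    rng = np.random.default_rng(np.random.SeedSequence([int(model.seed), 7]))
    spc = model.samples_per_condition
    n_samples = 2 * spc
    tfs, genes = model.tf_names, model.gene_names
    probe_ids = sorted(model.probe_map)
    probe_noise = 0.2 * model.noise_sd
    matrices = []
    for line_idx in range(n_cell_lines):
        cell = f"line{line_idx + 1}"
        tf_expr = model.baseline + rng.normal(size=(model.n_tfs, n_samples))
        tf_row = {tf: tf_expr[i] for i, tf in enumerate(tfs)}
        gene_expr: dict[str, np.ndarray] = dict(tf_row)
        for tf, members in model.regulon_map.items():
            for gene in sorted(members):
                w = model.weights[(tf, gene)]
                noise = rng.normal(scale=model.noise_sd, size=n_samples) if model.noise_sd > 0 else 0.0
                gene_expr[gene] = (
                    model.baseline + w * (tf_row[tf] - model.baseline) + noise
                )
        condition = np.array([UNDIFF] * spc + [DIFF] * spc)
        for gene in model.signature_genes:
            gene_expr[gene] = gene_expr[gene].copy()
            gene_expr[gene][spc:] += model.effect_size
        rows = np.empty((len(probe_ids), n_samples))
        for r, probe in enumerate(probe_ids):
            base = gene_expr[model.probe_map[probe]]
            jitter = (
                rng.normal(scale=probe_noise, size=n_samples)
                if probe_noise > 0
                else 0.0
            )
            rows[r] = base + jitter
        sample_ids = [
            f"{cell}_{'u' if c == UNDIFF else 'd'}{i % spc + 1:03d}"
            for i, c in enumerate(condition)
        ]
        matrices.append(
            ExpressionMatrix(
                data=pd.DataFrame(rows, index=probe_ids, columns=sample_ids),
                condition=pd.Series(condition, index=sample_ids),
                cell_line=cell,
            )
        )
    return matrices, model


# ---------------------------------------------------------------------------
# genome fixture (promoters, TFBS, window sequence, PWMs)
# ---------------------------------------------------------------------------


def default_pwms() -> list[PWM]:
    """Three strong retinoid-receptor-like matrices (direct/inverted repeats)."""

    def from_consensus(word: str, matrix_id: str, strength: float = 30.0) -> PWM:
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        counts = np.ones((4, len(word)))
        for col, base in enumerate(word):
            counts[idx[base], col] = strength
        return PWM(counts=counts, matrix_id=matrix_id)

    return [
        from_consensus("AGGTCAAGGTCA", "M1_DR0"),
        from_consensus("AGGTCATTTTTAGGTCA", "M2_DR5"),
        from_consensus("AGGTCATGACCT", "M3_IR0"),
    ]


@dataclass
class GenomeFixture:
    pwms: list[PWM]
    window: str
    planted_sites: dict[str, list[int]]
    cluster_count: int
    promoters: dict[str, GenomicInterval]
    genes: dict[str, GenomicInterval]
    tfbs: dict[str, list[GenomicInterval]]
    bound_edges: set[tuple[str, str]]
    unbound_tf: str
    anchor_gene: GenomicInterval


def promoter_window(
    gene: GenomicInterval, upstream: int = 2000, downstream: int = 500
) -> GenomicInterval:
    """Strand-aware promoter interval around the TSS."""
    if gene.strand == "-":
        start, end = gene.end - downstream, gene.end + upstream
    else:
        start, end = gene.start - upstream, gene.start + downstream
    return GenomicInterval(
        chrom=gene.chrom,
        start=max(start, 0),
        end=end,
        name=gene.name,
        strand=gene.strand,
    )


def generate_genome_fixture(
    seed: int, model: PlantedModel | None = None
) -> GenomeFixture:
    """Promoter/TFBS coordinates and a 400-bp scan window with planted motifs.

    One motif instance per matrix is planted at a recorded offset, in
    three well-separated groups (gap > merge default of 50 bp between
    groups).  One TF receives no binding sites at all, as a negative
    control for the promoter filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    if model is None:
        model = plant_structure(PlantedModel(seed=seed))
    elif not model.regulon_map:
        model = plant_structure(model)
    pwms = default_pwms()
    window = "".join(rng.choice(list("ACGT"), size=400))
    plant_at = {"M1_DR0": [40, 310], "M2_DR5": [70], "M3_IR0": [180]}
    for matrix_id, positions in plant_at.items():
        pwm = next(p for p in pwms if p.matrix_id == matrix_id)
        word = pwm.consensus()
        for pos in positions:
            window = window[:pos] + word + window[pos + len(word) :]
    # gene bodies laid out every 10 kb, alternating strand
    genes: dict[str, GenomicInterval] = {}
    for i, name in enumerate(model.tf_names + model.gene_names):
        start = 10_000 + 10_000 * i
        genes[name] = GenomicInterval(
            chrom="chr1",
            start=start,
            end=start + 2_000,
            name=name,
            strand="+" if i % 2 == 0 else "-",
        )
    promoters = {name: promoter_window(iv) for name, iv in genes.items()}
    unbound_tf = model.tf_names[-1]
    tfbs: dict[str, list[GenomicInterval]] = {tf: [] for tf in model.tf_names}
    bound_edges: set[tuple[str, str]] = set()
    for tf, gene in sorted(model.planted_edges):
        if tf == unbound_tf:
            continue
        promoter = promoters[gene]
        pos = int(rng.integers(promoter.start, promoter.end - 10))
        tfbs[tf].append(
            GenomicInterval(
                chrom=promoter.chrom, start=pos, end=pos + 10, name=tf
            )
        )
        bound_edges.add((tf, gene))
    anchor = GenomicInterval(
        chrom="chr9", start=1_000_000, end=1_350_000, name="NTRK2", strand="+"
    )
    return GenomeFixture(
        pwms=pwms,
        window=window,
        planted_sites=plant_at,
        cluster_count=3,
        promoters=promoters,
        genes=genes,
        tfbs=tfbs,
        bound_edges=bound_edges,
        unbound_tf=unbound_tf,
        anchor_gene=anchor,
    )


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

DEFAULT_GROUPS = ("C", "SF", "ATRA+_48h", "ATRA+_6d", "ATRA-_48h", "ATRA-_6d")


def generate_qpcr_tables(
    seed: int,
    true_fold_changes: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    sigma_ct: float = 0.1,
    reference_gene: str = "GAPDH",
    control_group: str = "C",
    ref_ct: float = 20.0,
    target_base_ct: float = 25.0,
) -> CtTable:
    """Simulate a long-format Ct table.

    ``true_fold_changes[gene][group]`` is the expression of ``gene`` in
    ``group`` relative to the control group; the target Ct decreases by
    one cycle per doubling (``Ct = base - log2(fold) + noise``).  The
    reference gene is emitted in every group with fold forced to 1.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    groups = sorted(
        {g for folds in true_fold_changes.values() for g in folds} | {control_group}
    )
    rows = []
    for group in groups:
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(scale=sigma_ct) if sigma_ct > 0 else 0.0
            rows.append(
                {
                    "sample_group": group,
                    "gene": reference_gene,
                    "replicate": rep,
                    "ct": ref_ct + noise,
                }
            )
            for gene in sorted(true_fold_changes):
                fold = float(true_fold_changes[gene].get(group, 1.0))
                if group == control_group:
                    fold = 1.0
                noise = rng.normal(scale=sigma_ct) if sigma_ct > 0 else 0.0
                rows.append(
                    {
                        "sample_group": group,
                        "gene": gene,
                        "replicate": rep,
                        "ct": target_base_ct - np.log2(fold) + noise,
                    }
                )
    return CtTable(rows=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# homolog fixture
# ---------------------------------------------------------------------------

DEFAULT_DIVERGENCE = {
    "human": 0.0,
    "orangutan": 0.02,
    "monkey": 0.05,
    "horse": 0.15,
    "pig": 0.30,
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class HomologFixture:
    alignment: dict[str, str]
    hits: dict[str, GenomicInterval]
    anchors: dict[str, GenomicInterval]
    classes: dict[str, str]
    divergence: dict[str, float]
    master: str


def generate_homolog_fixture(
    seed: int,
    divergence: Mapping[str, float] | None = None,
    master_len: int = 118,
    transition_fraction: float = 2.0 / 3.0,
) -> HomologFixture:
    """Mutated copies of a master element plus per-species coordinates.

    Sequences are substitution-only (hence already aligned).  Hit
    coordinates realise the position classes relative to each species'
    anchor gene: inside (human), downstream (orangutan, monkey),
    upstream (horse, via a minus-strand gene) and distal (pig).
    """
    div = dict(DEFAULT_DIVERGENCE if divergence is None else divergence)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    master = "".join(rng.choice(list("ACGT"), size=master_len))
    alignment: dict[str, str] = {}
    for species in div:
        seq = list(master)
        for i in range(master_len):
            if rng.random() < div[species]:
                if rng.random() < transition_fraction:
                    seq[i] = _TRANSITION[seq[i]]
                else:
                    seq[i] = rng.choice(_TRANSVERSIONS[seq[i]])
        alignment[species] = "".join(seq)

    L = master_len
    gene_plus = dict(chrom="chr9", start=1_000_000, end=1_350_000, name="NTRK2")
    anchors = {
        "human": GenomicInterval(**gene_plus, strand="+"),
        "orangutan": GenomicInterval(**gene_plus, strand="+"),
        "monkey": GenomicInterval(**gene_plus, strand="+"),
        "horse": GenomicInterval(**gene_plus, strand="-"),
        "pig": GenomicInterval(**gene_plus, strand="+"),
    }
    hits = {
        "human": GenomicInterval("chr9", 1_100_000, 1_100_000 + L, "hit", "+"),
        "orangutan": GenomicInterval("chr9", 1_355_000, 1_355_000 + L, "hit", "+"),
        "monkey": GenomicInterval("chr9", 1_370_000, 1_370_000 + L, "hit", "+"),
        # physically after a minus-strand gene = 5' of it
        "horse": GenomicInterval("chr9", 1_360_000, 1_360_000 + L, "hit", "+"),
        "pig": GenomicInterval("chr9", 100_000, 100_000 + L, "hit", "+"),
    }
    classes = {
        "human": "inside",
        "orangutan": "downstream",
        "monkey": "downstream",
        "horse": "upstream",
        "pig": "distal",
    }
    missing = set(div) - set(classes)
    for species in sorted(missing):  # extra species fall back to downstream
        offset = int(rng.integers(5_000, 100_000))
        hits[species] = GenomicInterval(
            "chr9", 1_350_000 + offset, 1_350_000 + offset + L, "hit", "+"
        )
        anchors[species] = GenomicInterval(**gene_plus, strand="+")
        classes[species] = "downstream"
    keep = set(div)
    return HomologFixture(
        alignment=alignment,
        hits={s: hits[s] for s in keep},
        anchors={s: anchors[s] for s in keep},
        classes={s: classes[s] for s in keep},
        divergence=div,
        master=master,
    )
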