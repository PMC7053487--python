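"""End-to-end discovery chain: DEGs -> signature -> networks -> MRA.

Mirrors the study flow: per cell line, probes are tested for
differential expression and collapsed to genes; genes differential in
every line form the signature; a bootstrap-consensus MI network is
inferred per line over candidate TFs and signature targets; master
regulators are called per line, intersected into common MRs, and the
edge-level intersection of the line networks (optionally filtered by
TF-promoter binding) yields the common regulatory network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .diffexpr import SignatureSet, call_degs, collapse_probes, intersect_signatures
from .io import (
    ExpressionMatrix,
    GenomicInterval,
    read_condition_map,
    read_expression_matrix,
    write_condition_map,
    write_expression_matrix,
)
from .mra import CommonNetwork, assemble_common_network, common_mrs, mra_table
from .netinf import Network, bootstrap_consensus, extract_regulons
from .simulate import PlantedModel, generate_expression_dataset


def derive_seed(seed: int, *salt: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([int(seed), *salt]).generate_state(1)[0] % 2**31)


@dataclass
class LineResult:
    cell_line: str
    probe_degs: pd.DataFrame
    gene_degs: pd.DataFrame
    gene_matrix: ExpressionMatrix
    network: Network | None = None
    mra: pd.DataFrame | None = None
    mrs: set[str] = field(default_factory=set)


@dataclass
class DiscoveryResult:
    lines: list[LineResult]
    signature: SignatureSet
    common_mr_set: set[str]
    common_network: CommonNetwork


def collapse_matrix(
    matrix: ExpressionMatrix, gene_degs: pd.DataFrame
) -> ExpressionMatrix:
    """Gene-level matrix using the representative probe chosen per gene."""
    chosen = gene_degs.set_index("gene")["probe"]
    data = matrix.data.loc[chosen.to_numpy()].copy()
    data.index = chosen.index
    return ExpressionMatrix(
        data=data.sort_index(),
        condition=matrix.condition,
        cell_line=matrix.cell_line,
    )


def run_discovery(
    matrices: Sequence[ExpressionMatrix],
    probe_map: Mapping[str, str],
    tf_list: Sequence[str],
    config: PipelineConfig | None = None,
    promoters: Mapping[str, GenomicInterval] | None = None,
    tfbs: Mapping[str, Sequence[GenomicInterval]] | None = None,
) -> DiscoveryResult:
    """Run the full discovery chain over >=2 cell-line matrices."""
    cfg = config or PipelineConfig()
    lines: list[LineResult] = []
    for i, matrix in enumerate(matrices):
        degs = call_degs(
            matrix,
            fc_hi=cfg.fc_hi,
            fc_lo=cfg.fc_lo,
            fdr_max=cfg.fdr_max,
            n_perm=cfg.n_perm,
            seed=derive_seed(cfg.seed, 101, i),
        )
        gene_degs = collapse_probes(degs, probe_map)
        lines.append(
            LineResult(
                cell_line=matrix.cell_line or f"line{i + 1}",
                probe_degs=degs,
                gene_degs=gene_degs,
                gene_matrix=collapse_matrix(matrix, gene_degs),
            )
        )
    signature = intersect_signatures([ln.gene_degs for ln in lines])

    tf_set = set(tf_list)
    for i, ln in enumerate(lines):
        present = set(ln.gene_matrix.probe_ids)
        targets = sorted((signature.genes - tf_set) & present)
        ln.network = bootstrap_consensus(
            ln.gene_matrix,
            tf_list=[t for t in tf_list if t in present],
            targets=targets,
            n_boot=cfg.n_boot,
            seed=derive_seed(cfg.seed, 202, i),
            consensus_min=cfg.consensus_min,
            alpha=cfg.mi_alpha,
            n_null=cfg.mi_n_perm,
            dpi_tolerance=cfg.dpi_tolerance,
        )
        regulons = extract_regulons(ln.network)
        universe = ln.gene_matrix.probe_ids
        ln.mra = mra_table(
            regulons, signature.genes, universe, fdr_max=cfg.mra_fdr_max
        )
        ln.mrs = set(ln.mra.loc[ln.mra["is_mr"], "tf"])

    common = common_mrs([ln.mrs for ln in lines])
    common_network = assemble_common_network(
        [ln.network for ln in lines],
        common,
        signature.genes,
        promoters=promoters,
        tfbs=tfbs,
    )
    return DiscoveryResult(
        lines=lines,
        signature=signature,
        common_mr_set=common,
        common_network=common_network,
    )


# ---------------------------------------------------------------------------
# simulated input bundles on disk
# ---------------------------------------------------------------------------


def write_bundle(
    outdir: str | Path,
    matrices: Sequence[ExpressionMatrix],
    model: PlantedModel,
) -> None:
    """Write a simulated expression bundle plus its ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        write_expression_matrix(m, outdir / f"{m.cell_line}_expr.tsv")
        write_condition_map(m, outdir / f"{m.cell_line}_conditions.tsv")
    pd.Series(model.probe_map, name="gene").to_csv(
        outdir / "probe_map.tsv", sep="\t", index_label="probe"
    )
    (outdir / "tf_list.txt").write_text("\n".join(model.tf_names) + "\n")
    truth = {
        "seed": model.seed,
        "cell_lines": [m.cell_line for m in matrices],
        "master_tfs": sorted(model.master_tfs),
        "signature_genes": sorted(model.signature_genes),
        "planted_edges": sorted([list(e) for e in model.planted_edges]),
        "regulons": {tf: sorted(v) for tf, v in model.regulon_map.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def read_bundle(
    indir: str | Path,
) -> tuple[list[ExpressionMatrix], dict[str, str], list[str], dict]:
    """Read back a bundle: matrices, probe map, TF list, truth manifest."""
    indir = Path(indir)
    truth = json.loads((indir / "truth.json").read_text())
    matrices = []
    for cell in truth["cell_lines"]:
        cond = read_condition_map(indir / f"{cell}_conditions.tsv")
        matrices.append(
            read_expression_matrix(
                indir / f"{cell}_expr.tsv",
                format="tsv",
                condition_map=cond,
                cell_line=cell,
            )
        )
    probe_map = (
        pd.read_csv(indir / "probe_map.tsv", sep="\t", index_col=0)["gene"].to_dict()
    )
    tf_list = (indir / "tf_list.txt").read_text().split()
    return matrices, probe_map, tf_list, truth


def simulate_bundle(
    outdir: str | Path, model: PlantedModel | None = None, n_cell_lines: int = 3
) -> PlantedModel:
    matrices, model = generate_expression_dataset(
        model or PlantedModel(), n_cell_lines=n_cell_lines
    )
    write_bundle(outdir, matrices, model)
    return model
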