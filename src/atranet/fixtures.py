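"""Packaged transcriptions of the published result tables.

``common_network_genes.tsv`` lists the reported common regulatory
network of retinoid-induced neuroblastoma differentiation: the 10
master-regulator TFs shared by all three cell lines and their 71
signature target genes (the published table lists node memberships,
not individual edges).  ``qpcr_primers.tsv`` is the RT-qPCR primer
panel: 19 assayed genes (15 neuron-projection genes, 3 neuronal
markers, beta-actin) plus the GAPDH internal reference.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mra import CommonNetwork


def _data_path(name: str):
    return resources.files("atranet").joinpath("data", name)


def load_common_network() -> CommonNetwork:
    """The published common network's node sets (edges not published)."""
    with resources.as_file(_data_path("common_network_genes.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    regulators = set(df.loc[df["role"] == "regulator", "gene"])
    targets = set(df.loc[df["role"] == "target", "gene"])
    return CommonNetwork(regulators=regulators, targets=targets)


def load_qpcr_primers() -> pd.DataFrame:
    """Primer panel with a ``role`` column; non-reference rows were assayed."""
    with resources.as_file(_data_path("qpcr_primers.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def assayed_genes() -> list[str]:
    primers = load_qpcr_primers()
    return list(primers.loc[primers["role"] != "reference", "gene"])
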