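"""Pipeline configuration: every tunable threshold with its study default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, Tuple

import yaml

from .consensus import DEFAULT_QUORUMS

__all__ = ["PipelineConfig", "DEFAULT_MOTIFS"]

#: IUPAC consensus patterns per TF. The RUNX site RCCRCA is the canonical
#: consensus; the Brn3a/Isl1 entries are synthetic placeholder consensi
#: (POU- and LIM-homeodomain AT-rich cores), NOT the proprietary Genomatix
#: V$BRNF / V$LHXF definitions, and are meant for synthetic-data runs. Real
#: analyses should override them in the config.
DEFAULT_MOTIFS: Dict[str, str] = {
    "Runx3": "RCCRCA",
    "Brn3a": "ATAATTAA",
    "Isl1": "CTAATGG",
}


@dataclass
class PipelineConfig:
    # consensus
    quorum_table: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_QUORUMS)
    )
    share_frac: float = 0.5
    repeat_max_frac: float = 0.6
    # motif patterns (IUPAC), scanned on both strands
    motifs: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    # width normalisation before overlap classification
    tf_extend: int = 300
    k27_extend: int = 300
    atac_extend: int = 500
    # promoter window around the TSS
    promoter_up: int = 1000
    promoter_down: int = 1000
    # regulatory domains (basal plus extension)
    basal_up: int = 5000
    basal_down: int = 1000
    max_ext: int = 1_000_000
    # DEG thresholds (relaxed preset; the strict preset is 2.0 / 0.05 on FDR)
    min_fc: float = 1.8
    max_padj: float = 0.05
    # HCT eligible region
    include_cds_exons: bool = False
    # clustering
    kmeans_k_up: int = 4
    kmeans_k_down: int = 2
    kmeans_n_init: int = 10

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        if "quorum_table" in data:
            cfg.quorum_table = {k: tuple(v) for k, v in data["quorum_table"].items()}
        return cfg
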