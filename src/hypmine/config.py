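"""Rule configuration shared across the mining pipeline.

Every threshold that drives an HRGP call or a downstream statistic lives in
one :class:`RuleConfig` so that a run can be reproduced from a single JSON
document.  Precedence when running the CLI is defaults < config file < flags.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

#: The ordered rule cascade used by the classifier.  First match wins.
DEFAULT_RULE_ORDER: tuple[str, ...] = (
    "FLA",
    "EXT_AGP",
    "LYS_RICH_AGP",
    "AG_PEPTIDE",
    "CLASSICAL_AGP",
    "SPN_EXT",
    "PRP",
)


@dataclass
class RuleConfig:
    """Thresholds and switches for HRGP identification and downstream stats.

    Attributes
    ----------
    past_agp
        Minimum PAST (P+A+S+T) fraction for the AGP-family rules.  Inclusive.
    past_classical
        Minimum PAST fraction for classical AGPs.  Inclusive.
    ag_peptide_max_len
        Maximum residue length for AG peptides (inclusive).
    min_ext_hits
        Minimum number of SPn motif hits for an extensin call.
    ext_same_n
        If true (default), the ``min_ext_hits`` extensin hits must share the
        same n; otherwise hits of any n in {3,4,5} are pooled.
    lys_min_hits, lys_window
        A lysine-rich region requires at least ``lys_min_hits`` lysine-motif
        hits starting within any ``lys_window``-residue span.
    fla_evalue
        Maximum hmmsearch independent E-value for a fasciclin domain hit.
    fla_accessions
        Pfam accessions accepted as fasciclin-family domains.
    prp_fifth_position
        Residues accepted at the fifth position of the PPV[X]? motif.
    rule_order
        Permutation of the rule names; evaluated first-match-wins.
    lam
        Synonymous substitution rate per site per year used for dating.
    wgd_window
        Closed Ks interval flagged as the recent whole-genome duplication.
    heatmap_bound
        Symmetric bound for heat-map range normalisation.
    proximal_max_rank_gap
        Maximum gene-rank distance for a proximal duplication call.
    """

    past_agp: float = 0.10
    past_classical: float = 0.30
    ag_peptide_max_len: int = 90
    min_ext_hits: int = 2
    ext_same_n: bool = True
    lys_min_hits: int = 2
    lys_window: int = 30
    fla_evalue: float = 1e-5
    fla_accessions: tuple[str, ...] = ("PF02469",)
    prp_fifth_position: tuple[str, ...] = ("K", "C")
    rule_order: tuple[str, ...] = DEFAULT_RULE_ORDER
    lam: float = 9.1e-9
    wgd_window: tuple[float, float] = (0.15, 0.3)
    heatmap_bound: float = 3.0
    proximal_max_rank_gap: int = 10

    def __post_init__(self) -> None:
        for name in ("past_agp", "past_classical"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.wgd_window[0] >= self.wgd_window[1]:
            raise ValueError("wgd_window low must be < high")
        if self.lam <= 0:
            raise ValueError("lam (substitution rate) must be positive")
        if self.heatmap_bound <= 0:
            raise ValueError("heatmap_bound must be positive")
        if sorted(self.rule_order) != sorted(DEFAULT_RULE_ORDER):
            raise ValueError(
                "rule_order must be a permutation of "
                + ", ".join(DEFAULT_RULE_ORDER)
            )
        self.rule_order = tuple(self.rule_order)
        self.fla_accessions = tuple(self.fla_accessions)
        self.prp_fifth_position = tuple(self.prp_fifth_position)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rule_order"] = list(self.rule_order)
        d["fla_accessions"] = list(self.fla_accessions)
        d["prp_fifth_position"] = list(self.prp_fifth_position)
        d["wgd_window"] = list(self.wgd_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RuleConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RuleConfig keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "wgd_window" in kwargs:
            kwargs["wgd_window"] = tuple(kwargs["wgd_window"])
        for key in ("rule_order", "fla_accessions", "prp_fifth_position"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **changes) -> "RuleConfig":
        return dataclasses.replace(self, **changes)
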