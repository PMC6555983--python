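"""Study configuration: day-count rules, code sets, catalog, AE definitions.

Everything the eligibility, line-of-therapy, washout and incidence rules
parameterize on lives in one :class:`StudyConfig`, loaded from the bundled
default YAML and optionally overlaid with a user file.  The bundled AE,
nephrectomy, other-primary and comorbidity code lists are synthetic
defaults for use with the synthetic generator; real-data analyses are
expected to supply their own.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .claims_model import AEDefinition, CodeSet, DrugCatalog, default_catalog


@dataclass(frozen=True)
class RuleParameters:
    """All day-count knobs of the episode/eligibility/washout rules."""

    gap_days: int = 90
    switch_window_days: int = 30
    index_replace_window_days: int = 30
    combination_window_days: int = 30
    five_day_exclusion_days: int = 5
    washout_acute_days: int = 30
    washout_chronic_days: int = 365
    enrollment_pre_days: int = 180
    enrollment_post_days: int = 180
    baseline_days: int = 180
    ae_post_treatment_days: int = 30
    tcc_pre_index_days: int = 30
    index_window: tuple[pd.Timestamp, pd.Timestamp] = (
        pd.Timestamp("2011-01-01"),
        pd.Timestamp("2015-12-31"),
    )
    dx_window_pad_before_days: int = 184
    dx_window_pad_after_days: int = 273

    def __post_init__(self) -> None:
        for name in (
            "gap_days", "switch_window_days", "index_replace_window_days",
            "combination_window_days", "five_day_exclusion_days",
            "washout_acute_days", "washout_chronic_days",
            "enrollment_pre_days", "enrollment_post_days", "baseline_days",
            "ae_post_treatment_days", "tcc_pre_index_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.index_window
        if lo > hi:
            raise ValueError("index_window must be well-ordered")

    @property
    def dx_window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        lo, hi = self.index_window
        return (
            lo - pd.Timedelta(days=self.dx_window_pad_before_days),
            hi + pd.Timedelta(days=self.dx_window_pad_after_days),
        )


@dataclass
class StudyConfig:
    params: RuleParameters
    catalog: DrugCatalog
    kidney: CodeSet
    metastasis: dict[str, CodeSet]
    comorbidity: dict[str, CodeSet]
    other_primary: dict[str, CodeSet]
    nephrectomy_procedures: CodeSet
    tcc_agents: tuple[str, ...]
    ae_definitions: list[AEDefinition] = field(default_factory=list)

    def ae(self, name: str) -> AEDefinition:
        for d in self.ae_definitions:
            if d.ae_name == name:
                return d
        raise KeyError(f"no AE definition named {name!r}")

    def manifest(self) -> dict[str, Any]:
        """Flat record of every tunable parameter, for run manifests."""
        m: dict[str, Any] = {
            k: (str(v) if isinstance(v, (pd.Timestamp, tuple)) else v)
            for k, v in vars(self.params).items()
        }
        m["cycle_lengths"] = {
            e.agent: e.cycle_length_days for e in self.catalog if e.cycle_length_days
        }
        m["tcc_agents"] = list(self.tcc_agents)
        m["ae_definitions"] = {
            d.ae_name: {"chronic": d.chronic, "prefixes": list(d.code_set.prefixes)}
            for d in self.ae_definitions
        }
        m["kidney_prefixes"] = list(self.kidney.prefixes)
        return m


def _deep_update(base: dict, overlay: Mapping) -> dict:
    for k, v in overlay.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            base[k] = _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _codeset_map(name: str, raw: Mapping[str, list[str]]) -> dict[str, CodeSet]:
    return {k: CodeSet(f"{name}:{k}", tuple(v)) for k, v in raw.items()}


def load_study_config(path: str | Path | None = None) -> StudyConfig:
    """Load the bundled defaults, overlaid with ``path`` if given."""
    ref = importlib.resources.files("mrcc_claims") / "data" / "default_config.yaml"
    raw = yaml.safe_load(ref.read_text())
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        raw = _deep_update(raw, user)
    return build_study_config(raw)


def build_study_config(raw: Mapping[str, Any]) -> StudyConfig:
    p = dict(raw.get("parameters", {}))
    if "index_window" in p:
        lo, hi = p["index_window"]
        p["index_window"] = (pd.Timestamp(lo), pd.Timestamp(hi))
    params = RuleParameters(**p)
    catalog = default_catalog(raw.get("catalog", {}).get("cycle_lengths"))
    cs = raw["code_sets"]
    aes = [
        AEDefinition(
            ae_name=d["name"],
            code_set=CodeSet(f"ae:{d['name']}", tuple(d["codes"])),
            chronic=bool(d.get("chronic", False)),
        )
        for d in raw.get("adverse_events", [])
    ]
    return StudyConfig(
        params=params,
        catalog=catalog,
        kidney=CodeSet("kidney_cancer", tuple(cs["kidney_cancer"])),
        metastasis=_codeset_map("metastasis", cs["metastasis"]),
        comorbidity=_codeset_map("comorbidity", cs["comorbidity"]),
        other_primary=_codeset_map("other_primary", cs["other_primary_cancer"]),
        nephrectomy_procedures=CodeSet(
            "nephrectomy", tuple(cs["nephrectomy_procedures"])
        ),
        tcc_agents=tuple(raw.get("tcc_agents", [])),
        ae_definitions=aes,
    )
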