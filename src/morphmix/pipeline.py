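"""Full analysis orchestration: screen → fit → classify → allometry → report.

The stage order mirrors the male-dimorphism workflow: kernel-density
bimodality screening and variance standardization per sex, a facing-gamma
mixture fit to the male trait, confidence-level classification of males
into morphs, and per-group SMA allometry with slope comparisons.  With too
few males for the seven-parameter mixture the run degrades to a
descriptive-only report with an explicit warning rather than failing.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources
from typing import Optional

import numpy as np

from . import __version__
from .allometry import GroupAllometry, allometry_by_group
from .descriptive import kde, variance_ratio
from .facing_gamma import (ClassificationRule, FitConfig, MixtureModel,
                           classify, model_compare)
from .io import MeasurementTable, Sex

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis",
           "load_report_schema", "validate_report"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for one pipeline run; defaults reproduce the published rule set."""

    level: float = 0.95
    rule: str = ClassificationRule.COMPONENT_QUANTILE.value
    alpha: float = 0.05
    min_males_for_mixture: int = 10
    fit_starts: int = 8
    seed: int = 0
    round_digits: int = 3

    def to_dict(self) -> dict:
        return {"level": self.level, "rule": self.rule, "alpha": self.alpha,
                "min_males_for_mixture": self.min_males_for_mixture,
                "fit_starts": self.fit_starts, "seed": self.seed,
                "round_digits": self.round_digits}


@dataclass
class AnalysisReport:
    """Machine-readable record of one full analysis."""

    input_summary: dict
    descriptive: dict
    mixture: Optional[dict]
    model_comparison: Optional[dict]
    classification: Optional[dict]
    allometry: Optional[dict]
    warnings: list[str]
    provenance: dict

    def to_dict(self, full_precision: bool = False) -> dict:
        doc = {
            "input_summary": self.input_summary,
            "descriptive": self.descriptive,
            "mixture": self.mixture,
            "model_comparison": self.model_comparison,
            "classification": self.classification,
            "allometry": self.allometry,
            "warnings": list(self.warnings),
            "provenance": self.provenance,
        }
        if not full_precision:
            digits = self.provenance.get("round_digits", 3)
            doc = _round_floats(doc, digits)
        return doc

    def to_json(self, full_precision: bool = False, **kwargs) -> str:
        return json.dumps(self.to_dict(full_precision=full_precision), **kwargs)


def _round_floats(obj, digits: int):
    if isinstance(obj, float):
        return round(obj, digits) if math.isfinite(obj) else obj
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_analysis(table: MeasurementTable,
                 config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Run every stage the input supports and embed all intermediates.

    Stage failures are recorded in ``warnings`` with context; stages that do
    not depend on the failed one still run.
    """
    if len(table) == 0:
        raise ValueError("empty table: nothing to analyse")
    adults = table.adults()
    warnings: list[str] = []

    counts: dict[str, dict[str, int]] = {}
    for rec in table:
        counts.setdefault(rec.species, {"male": 0, "female": 0, "juvenile": 0})
        counts[rec.species][rec.sex.value] += 1
    input_summary = {"n_records": len(table), "counts": counts,
                     "n_juveniles_excluded": len(table) - len(adults)}

    males = [r for r in adults if r.sex is Sex.MALE and r.usable]
    females = [r for r in adults if r.sex is Sex.FEMALE and r.usable]
    male_pat = np.array([r.patella_length for r in males])
    male_pro = np.array([r.prosoma_length for r in males])
    fem_pat = np.array([r.patella_length for r in females])
    fem_pro = np.array([r.prosoma_length for r in females])

    descriptive: dict = {"male": {}, "female": {}}
    for sex, pat, pro in (("male", male_pat, male_pro),
                          ("female", fem_pat, fem_pro)):
        for trait, xs in (("patella", pat), ("prosoma", pro)):
            try:
                descriptive[sex][f"kde_{trait}"] = kde(xs).to_dict()
            except ValueError as exc:
                warnings.append(f"KDE ({sex} {trait}): {exc}")
        try:
            descriptive[sex]["variance_comparison"] = variance_ratio(pat, pro).to_dict()
        except ValueError as exc:
            warnings.append(f"variance comparison ({sex}): {exc}")

    mixture_doc = comparison_doc = classification_doc = None
    classification = None
    fit_cfg = FitConfig(starts=config.fit_starts, seed=config.seed,
                        min_n=config.min_males_for_mixture)
    if male_pat.size < config.min_males_for_mixture:
        warnings.append(
            f"only {male_pat.size} usable males (< {config.min_males_for_mixture}): "
            "mixture fitting skipped, descriptive-only report")
    else:
        try:
            comparison = model_compare(male_pat, fit_cfg)
            comparison_doc = comparison.to_dict()
            mix = next((c.model for c in comparison.candidates
                        if c.name == "facing_mixture" and c.error is None), None)
            if mix is None:
                raise RuntimeError("facing mixture candidate failed to fit")
            assert isinstance(mix, MixtureModel)
            mixture_doc = mix.to_dict()
            classification = classify(mix, male_pat, level=config.level,
                                      rule=config.rule)
            classification_doc = classification.to_dict()
        except Exception as exc:  # noqa: BLE001 — recorded with context
            warnings.append(f"mixture stage failed: {exc}")

    allometry_doc = None
    try:
        groups: GroupAllometry = allometry_by_group(
            adults, classification, alpha=config.alpha)
        allometry_doc = groups.to_dict()
        warnings.extend(groups.warnings)
    except Exception as exc:  # noqa: BLE001
        warnings.append(f"allometry stage failed: {exc}")

    provenance = {
        "software": "morphmix", "version": __version__,
        "config": config.to_dict(), "config_hash": _config_hash(config),
        "seed": config.seed, "round_digits": config.round_digits,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return AnalysisReport(
        input_summary=input_summary, descriptive=descriptive,
        mixture=mixture_doc, model_comparison=comparison_doc,
        classification=classification_doc, allometry=allometry_doc,
        warnings=warnings, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Report schema
# ---------------------------------------------------------------------------

def load_report_schema() -> dict:
    """The JSON schema document shipped with the package."""
    text = resources.files("morphmix").joinpath(
        "schemas/report_schema.json").read_text()
    return json.loads(text)


def _check(instance, schema, path="$") -> list[str]:
    """Minimal JSON-schema subset checker: type, required, properties, items."""
    errors: list[str] = []
    t = schema.get("type")
    type_map = {"object": dict, "array": list, "string": str,
                "number": (int, float), "integer": int, "boolean": bool,
                "null": type(None)}
    if t is not None:
        types = t if isinstance(t, list) else [t]
        if not any(isinstance(instance, type_map[tt]) and
                   not (tt == "number" and isinstance(instance, bool))
                   for tt in types):
            errors.append(f"{path}: expected {t}, got {type(instance).__name__}")
            return errors
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{path}.{key}"))
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            errors.extend(_check(item, schema["items"], f"{path}[{i}]"))
    return errors


def validate_report(doc: dict) -> list[str]:
    """Return schema violations for a report document (empty = valid)."""
    return _check(doc, load_report_schema())
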