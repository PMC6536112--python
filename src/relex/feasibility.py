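"""End-to-end feasibility assessment from a study-description file.

A study file (JSON or YAML) describes a published test-retest study, the
expected spread of the planned sample, and optionally the planned design.
``run_feasibility`` composes the toolkit: ICC extrapolation, smallest
detectable differences, threshold classification, effect-size attenuation
and power analysis, returning one serializable result.

Schema (keys in brackets optional)::

    trt:    {mean, sd, icc | sem, [n], [k]}
    new:    {sd | sd_ratio | groups: {n1, mean1, sd1, n2, mean2, sd2}}
    [tau]:  SEM inflation factor, default 1
    [design]:
        kind: correlation | one_sample_t | paired_t | two_sample_t
        correlation: {rel_other, max_r2_biological}
        t families:  {d_true, [n1], [n2]}
        common:      {[alpha]=0.05, [power]=0.8, [sides]=two}

For a change-score outcome, supply the change-score SEM directly as
``trt.sem`` (error variance of a difference is twice the single-measurement
error variance) and the change-score SD (or groups of change scores) under
``new``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import effect_size, power
from .extrapolation import (ASSUMPTIONS, NONPOSITIVE_FLAG, ExtrapolationSpec,
                            extrapolate_icc)
from .group_composition import GroupSpec, combined_sample_sd
from .variance_components import (TestRetestSummary, classify_reliability,
                                  sdd_group, sdd_individual)

T_KINDS = ("one_sample_t", "paired_t", "two_sample_t")


class InvalidStudyFileError(ValueError):
    """Study description failed validation; message says which key and why."""


@dataclass
class FeasibilityResult:
    """Aggregate answer: can the planned study answer its question?"""

    extrapolated_icc: float
    attenuation: float | None
    n_required: int | None
    n_unattenuated: int | None
    sdd_individual: float
    sdd_group: float
    classification: dict
    flags: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "extrapolated_icc": self.extrapolated_icc,
            "attenuation": self.attenuation,
            "n_required": self.n_required,
            "n_unattenuated": self.n_unattenuated,
            "sdd_individual": self.sdd_individual,
            "sdd_group": self.sdd_group,
            "classification": dict(self.classification),
            "flags": list(self.flags),
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise InvalidStudyFileError(f"missing key {key!r} in {context}")
    return mapping[key]


def _number(mapping: dict, key: str, context: str) -> float:
    value = _require(mapping, key, context)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise InvalidStudyFileError(
            f"{context}.{key} must be a number, got {value!r}")
    return float(value)


def load_study(path) -> dict:
    """Parse a JSON or YAML study description into a dict."""
    path = Path(path)
    if not path.exists():
        raise InvalidStudyFileError(f"study file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            study = yaml.safe_load(text)
        else:
            study = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise InvalidStudyFileError(f"could not parse {path.name}: {exc}") from exc
    if not isinstance(study, dict):
        raise InvalidStudyFileError("study file must contain a mapping")
    return study


def _parse_trt(study: dict) -> TestRetestSummary:
    trt = _require(study, "trt", "study")
    if not isinstance(trt, dict):
        raise InvalidStudyFileError("'trt' must be a mapping")
    kwargs = dict(
        mean=_number(trt, "mean", "trt"),
        sd=_number(trt, "sd", "trt"),
        n=int(trt.get("n", 2)),
        k=int(trt.get("k", 2)),
    )
    if "icc" in trt:
        kwargs["icc"] = _number(trt, "icc", "trt")
    if "sem" in trt:
        kwargs["sem"] = _number(trt, "sem", "trt")
    if "icc" not in kwargs and "sem" not in kwargs:
        raise InvalidStudyFileError("trt needs at least one of 'icc', 'sem'")
    try:
        return TestRetestSummary(**kwargs)
    except ValueError as exc:
        raise InvalidStudyFileError(f"invalid trt block: {exc}") from exc


def _parse_sd_new(study: dict, trt: TestRetestSummary) -> tuple[float, dict]:
    new = _require(study, "new", "study")
    if not isinstance(new, dict):
        raise InvalidStudyFileError("'new' must be a mapping")
    keys = [k for k in ("sd", "sd_ratio", "groups") if k in new]
    if len(keys) != 1:
        raise InvalidStudyFileError(
            "'new' needs exactly one of 'sd', 'sd_ratio', 'groups'")
    if keys[0] == "sd":
        return _number(new, "sd", "new"), {"sd_new_source": "sd"}
    if keys[0] == "sd_ratio":
        ratio = _number(new, "sd_ratio", "new")
        if ratio <= 0:
            raise InvalidStudyFileError("new.sd_ratio must be > 0")
        return ratio * trt.sd, {"sd_new_source": "sd_ratio", "sd_ratio": ratio}
    groups = new["groups"]
    if not isinstance(groups, dict):
        raise InvalidStudyFileError("'new.groups' must be a mapping")
    try:
        g1 = GroupSpec(n=int(_number(groups, "n1", "new.groups")),
                       mean=_number(groups, "mean1", "new.groups"),
                       sd=_number(groups, "sd1", "new.groups"))
        g2 = GroupSpec(n=int(_number(groups, "n2", "new.groups")),
                       mean=_number(groups, "mean2", "new.groups"),
                       sd=_number(groups, "sd2", "new.groups"))
    except ValueError as exc:
        raise InvalidStudyFileError(f"invalid new.groups block: {exc}") from exc
    sd_new = combined_sample_sd(g1, g2)
    return sd_new, {"sd_new_source": "groups",
                    "groups": dict(groups), "combined_sd": sd_new}


def run_feasibility(study_file) -> FeasibilityResult:
    """Run the full feasibility workflow for one study description."""
    study = load_study(study_file)
    trt = _parse_trt(study)
    sd_new, sd_prov = _parse_sd_new(study, trt)
    tau = float(study.get("tau", 1.0))
    try:
        spec = ExtrapolationSpec(trt=trt, sd_new=sd_new, tau=tau,
                                 allow_deflation=bool(study.get("allow_deflation", False)))
    except ValueError as exc:
        raise InvalidStudyFileError(str(exc)) from exc
    extr = extrapolate_icc(spec)
    flags = list(extr.flags)

    sigma_e = tau * trt.sem_effective
    design = study.get("design")
    group_n = 2
    if isinstance(design, dict) and "n1" in design:
        group_n = int(design["n1"])
    sdd_ind = sdd_individual(sigma_e)
    sdd_grp = sdd_group(sigma_e, group_n)

    classification = {scheme: classify_reliability(extr.icc_new, scheme)
                      for scheme in ("koo_li", "nunnally", "fleiss", "cicchetti")}

    attenuation = n_required = n_unatten = None
    design_prov: dict = {}
    if design is not None:
        if not isinstance(design, dict):
            raise InvalidStudyFileError("'design' must be a mapping")
        kind = _require(design, "kind", "design")
        alpha = float(design.get("alpha", 0.05))
        pwr = float(design.get("power", 0.8))
        sides = str(design.get("sides", "two"))
        design_prov = {"kind": kind, "alpha": alpha, "power": pwr,
                       "sides": sides}
        if extr.icc_new <= 0:
            flags.append("power analysis skipped: non-positive extrapolated "
                         "reliability")
        elif kind == "correlation":
            rel_other = _number(design, "rel_other", "design")
            max_r2 = _number(design, "max_r2_biological", "design")
            try:
                feas = power.feasibility_correlation(
                    extr.icc_new, rel_other, max_r2, alpha, pwr, sides)
            except ValueError as exc:
                raise InvalidStudyFileError(str(exc)) from exc
            attenuation = feas.attenuation
            n_required = feas.n_attenuated.n_required
            n_unatten = feas.n_unattenuated.n_required
            design_prov.update(rel_other=rel_other, max_r2_biological=max_r2,
                               r_max=feas.r_max, r_observable=feas.r_observable)
        elif kind in T_KINDS:
            d_true = _number(design, "d_true", "design")
            n1 = int(design.get("n1", 1))
            n2 = int(design.get("n2", n1))
            d_obs = effect_size.attenuate_d(d_true, extr.icc_new, n1, n2)
            attenuation = d_obs / d_true if d_true != 0 else None
            n_required = power.n_for_t_test(abs(d_obs), kind, alpha, pwr,
                                            sides).n_required
            n_unatten = power.n_for_t_test(abs(d_true), kind, alpha, pwr,
                                           sides).n_required
            design_prov.update(d_true=d_true, d_observed=d_obs, n1=n1, n2=n2)
        else:
            raise InvalidStudyFileError(
                f"design.kind must be 'correlation' or one of {T_KINDS}")

    provenance = {
        "trt": {"mean": trt.mean, "sd": trt.sd, "icc": trt.icc,
                "sem": trt.sem, "n": trt.n, "k": trt.k,
                "sem_effective": trt.sem_effective},
        "tau": tau,
        "sd_new": sd_new,
        **sd_prov,
        "sigma_e_used_for_sdd": sigma_e,
        "sdd_group_n": group_n,
        "design": design_prov or None,
        "assumptions": list(ASSUMPTIONS),
        "conventions": {"correlation_n": power.CORR_ROUNDING,
                        "t_test_n": power.T_ROUNDING},
    }
    return FeasibilityResult(
        extrapolated_icc=extr.icc_new,
        attenuation=attenuation,
        n_required=n_required,
        n_unattenuated=n_unatten,
        sdd_individual=sdd_ind,
        sdd_group=sdd_grp,
        classification=classification,
        flags=flags,
        provenance=provenance,
    )
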