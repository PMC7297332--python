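"""Synthetic cath-lab dose-log generator.

Emulates the statistical structure of a 71-procedure interventional-
cardiology dose study: procedure types split 43/16/12 across CA-with-PCI /
CA / others, right-skewed per-procedure operator doses and DAP values with
configured means and SDs, truncated-normal technique factors, and a weak
positive coupling between DAP and operator dose (default R² targets 0.11
for the primary operator and 0.46 for the assistant).

Marginal doses and DAP default to log-normal, moment-matched so the
back-transformed arithmetic mean and SD equal the configured values exactly:
σ² = ln(1 + s²/m²), μ = ln m − σ²/2.  Coupling is imposed on the log scale —
ln(dose) = a + b·ln(DAP) + ε — which leaves the marginals log-normal; a
common within-type log-scale correlation ρ is solved numerically so the
*pooled* (across procedure types, weighted by type frequency and assistant
presence) population Pearson R² between DAP and dose equals the target, in
expectation.  A generated log therefore reproduces the configured R² on
average, not per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .dose_records import OperatorDose, ProcedureRecord, ProcedureType, Role, Sex

__all__ = [
    "DoseModel",
    "GeneratorConfig",
    "CouplingError",
    "calibrate_lognormal",
    "generate",
    "generate_frame",
]

_TYPES = (ProcedureType.CA_PCI, ProcedureType.CA, ProcedureType.OTHERS)
_TECH_FIELDS = (
    "fluoro_time_min",
    "fluoro_kv",
    "fluoro_ma",
    "acq_kv",
    "acq_ma",
    "acq_time_s",
)


class CouplingError(ValueError):
    """The requested DAP–dose R² is unattainable given the marginals."""


@dataclass(frozen=True)
class DoseModel:
    """Right-skewed non-negative marginal with given arithmetic mean/SD (μSv
    for doses, Gy·cm² for DAP)."""

    mean: float
    sd: float
    family: str = "lognormal"  # or "gamma"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")


def _default_dose_models() -> dict[tuple[ProcedureType, Role], DoseModel]:
    # Study means ± SDs per (procedure type × role).  The single-case
    # assistant "others" cell has no published SD; its default SD equals the
    # mean (CV 1, matching the CA-assistant cell's CV ≈ 1.01).
    return {
        (ProcedureType.CA_PCI, Role.PRIMARY): DoseModel(59.33, 95.03),
        (ProcedureType.CA, Role.PRIMARY): DoseModel(39.81, 103.85),
        (ProcedureType.OTHERS, Role.PRIMARY): DoseModel(21.92, 37.04),
        (ProcedureType.CA_PCI, Role.ASSISTANT): DoseModel(30.03, 55.67),
        (ProcedureType.CA, Role.ASSISTANT): DoseModel(14.67, 14.88),
        (ProcedureType.OTHERS, Role.ASSISTANT): DoseModel(4.0, 4.0),
    }


def _default_dap_models() -> dict[ProcedureType, DoseModel]:
    return {
        ProcedureType.CA_PCI: DoseModel(238.67, 201.51),
        ProcedureType.CA: DoseModel(119.30, 54.40),
        ProcedureType.OTHERS: DoseModel(49.82, 126.27),
    }


def _default_technique_models() -> dict[ProcedureType, dict[str, tuple[float, float]]]:
    return {
        ProcedureType.CA_PCI: {
            "fluoro_time_min": (14.67, 12.83),
            "fluoro_kv": (98.54, 16.55),
            "fluoro_ma": (12.31, 4.93),
            "acq_kv": (85.60, 14.94),
            "acq_ma": (784.75, 107.18),
            "acq_time_s": (53.16, 10.33),
        },
        ProcedureType.CA: {
            "fluoro_time_min": (6.10, 3.49),
            "fluoro_kv": (87.23, 15.06),
            "fluoro_ma": (15.62, 4.21),
            "acq_kv": (80.84, 13.91),
            "acq_ma": (733.46, 157.42),
            "acq_time_s": (41.31, 11.56),
        },
        ProcedureType.OTHERS: {
            "fluoro_time_min": (14.21, 12.73),
            "fluoro_kv": (93.61, 15.31),
            "fluoro_ma": (6.12, 2.93),
            "acq_kv": (83.40, 20.61),
            "acq_ma": (505.70, 300.73),
            "acq_time_s": (4.42, 5.23),
        },
    }


def _default_age_models() -> dict[tuple[ProcedureType, Role], tuple[float, float]]:
    return {
        (ProcedureType.CA_PCI, Role.PRIMARY): (49.25, 6.99),
        (ProcedureType.CA, Role.PRIMARY): (43.75, 3.30),
        (ProcedureType.OTHERS, Role.PRIMARY): (42.33, 2.08),
        (ProcedureType.CA_PCI, Role.ASSISTANT): (32.6, 3.58),
        (ProcedureType.CA, Role.ASSISTANT): (33.0, 4.58),
        (ProcedureType.OTHERS, Role.ASSISTANT): (32.0, 0.0),
    }


@dataclass
class GeneratorConfig:
    """Study-shaped generator configuration; defaults emulate the study."""

    n_procedures: int = 71
    seed: int = 0
    type_probabilities: tuple[float, float, float] = (43 / 71, 16 / 71, 12 / 71)
    dose_models: dict[tuple[ProcedureType, Role], DoseModel] = field(
        default_factory=_default_dose_models
    )
    dap_models: dict[ProcedureType, DoseModel] = field(default_factory=_default_dap_models)
    coupling_r2: dict[Role, float] = field(
        default_factory=lambda: {Role.PRIMARY: 0.11, Role.ASSISTANT: 0.46}
    )
    technique_models: dict[ProcedureType, dict[str, tuple[float, float]]] = field(
        default_factory=_default_technique_models
    )
    assistant_presence: dict[ProcedureType, float] = field(
        default_factory=lambda: {
            ProcedureType.CA_PCI: 38 / 43,
            ProcedureType.CA: 6 / 16,
            ProcedureType.OTHERS: 1 / 12,
        }
    )
    assistant_male_prob: dict[ProcedureType, float] = field(
        default_factory=lambda: {
            ProcedureType.CA_PCI: 0.4474,
            ProcedureType.CA: 0.8333,
            ProcedureType.OTHERS: 1.0,
        }
    )
    age_models: dict[tuple[ProcedureType, Role], tuple[float, float]] = field(
        default_factory=_default_age_models
    )
    # Projection labels use a flat default; real per-lab distributions vary
    # and no study values are hard-coded.
    beam_labels: tuple[str, ...] = ("LAO", "RAO", "AP", "CRAN", "CAU")
    beam_weights: tuple[float, ...] | None = None
    n_primary_operators: int = 6
    n_assistant_operators: int = 5

    def validate(self) -> None:
        probs = np.asarray(self.type_probabilities, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0):
            raise ValueError("type_probabilities must be 3 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"type_probabilities must sum to 1 (got {probs.sum()!r})"
            )
        for role, r2 in self.coupling_r2.items():
            if not (0 <= r2 < 1):
                raise ValueError(f"coupling R² for {Role(role).value} not in [0, 1)")
        for ptype, p in self.assistant_presence.items():
            if not (0 <= p <= 1):
                raise ValueError(f"assistant presence for {ptype} not in [0, 1]")
        if self.n_procedures < 1:
            raise ValueError("n_procedures must be >= 1")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_procedures": self.n_procedures,
            "seed": self.seed,
            "type_probabilities": list(self.type_probabilities),
            "dose_models": {
                f"{t.value}:{r.value}": {"mean": m.mean, "sd": m.sd, "family": m.family}
                for (t, r), m in self.dose_models.items()
            },
            "dap_models": {
                t.value: {"mean": m.mean, "sd": m.sd, "family": m.family}
                for t, m in self.dap_models.items()
            },
            "coupling_r2": {r.value: v for r, v in self.coupling_r2.items()},
            "technique_models": {
                t.value: {k: list(v) for k, v in d.items()}
                for t, d in self.technique_models.items()
            },
            "assistant_presence": {t.value: p for t, p in self.assistant_presence.items()},
            "assistant_male_prob": {
                t.value: p for t, p in self.assistant_male_prob.items()
            },
            "age_models": {
                f"{t.value}:{r.value}": list(v) for (t, r), v in self.age_models.items()
            },
            "beam_labels": list(self.beam_labels),
            "beam_weights": list(self.beam_weights) if self.beam_weights else None,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        cfg = cls()
        kwargs: dict = {}
        for key in ("n_procedures", "seed"):
            if key in data:
                kwargs[key] = int(data[key])
        if "type_probabilities" in data:
            kwargs["type_probabilities"] = tuple(float(x) for x in data["type_probabilities"])
        if "dose_models" in data:
            kwargs["dose_models"] = {
                _split_key(k): DoseModel(**v) for k, v in data["dose_models"].items()
            }
        if "dap_models" in data:
            kwargs["dap_models"] = {
                ProcedureType(k): DoseModel(**v) for k, v in data["dap_models"].items()
            }
        if "coupling_r2" in data:
            kwargs["coupling_r2"] = {
                Role(k): float(v) for k, v in data["coupling_r2"].items()
            }
        if "technique_models" in data:
            kwargs["technique_models"] = {
                ProcedureType(t): {k: tuple(v) for k, v in d.items()}
                for t, d in data["technique_models"].items()
            }
        if "assistant_presence" in data:
            kwargs["assistant_presence"] = {
                ProcedureType(k): float(v) for k, v in data["assistant_presence"].items()
            }
        if "assistant_male_prob" in data:
            kwargs["assistant_male_prob"] = {
                ProcedureType(k): float(v) for k, v in data["assistant_male_prob"].items()
            }
        if "age_models" in data:
            kwargs["age_models"] = {
                _split_key(k): tuple(v) for k, v in data["age_models"].items()
            }
        if "beam_labels" in data:
            kwargs["beam_labels"] = tuple(data["beam_labels"])
        if data.get("beam_weights"):
            kwargs["beam_weights"] = tuple(float(x) for x in data["beam_weights"])
        return replace(cfg, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)


def _split_key(key: str) -> tuple[ProcedureType, Role]:
    tname, _, rname = key.partition(":")
    return ProcedureType(tname), Role(rname)


# ---------------------------------------------------------------------------
# Moment matching and coupling calibration
# ---------------------------------------------------------------------------

def calibrate_lognormal(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (location, scale) whose back-transform has the requested
    arithmetic mean and SD.

    Uses σ² = ln(1 + s²/m²), μ = ln m − σ²/2.  ``sd = 0`` degenerates to a
    point mass at ``mean`` (scale 0).
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _lognormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Arithmetic mean and variance of exp(N(mu, sigma²))."""
    m = math.exp(mu + sigma**2 / 2.0)
    v = m * m * (math.exp(sigma**2) - 1.0)
    return m, v


@dataclass(frozen=True)
class _TypeCoupling:
    """Per-type log-linear coupling: ln(dose) = a + b·ln(DAP) + N(0, sd_eps²)."""

    a: float
    b: float
    sd_eps: float
    mu_y: float
    sigma_y: float


def _pooled_corr(rho: float, comps: list[dict]) -> float:
    """Population Pearson correlation of the (DAP, dose) mixture when every
    type shares log-scale correlation ``rho``."""
    ex = ey = exy = ex2 = ey2 = 0.0
    for c in comps:
        w = c["w"]
        ex += w * c["mx"]
        ey += w * c["my"]
        ex2 += w * (c["vx"] + c["mx"] ** 2)
        ey2 += w * (c["vy"] + c["my"] ** 2)
        cov_k = c["mx"] * c["my"] * (math.exp(rho * c["sx"] * c["sy"]) - 1.0)
        exy += w * (cov_k + c["mx"] * c["my"])
    var_x = ex2 - ex * ex
    var_y = ey2 - ey * ey
    if var_x <= 0 or var_y <= 0:
        return 0.0
    return (exy - ex * ey) / math.sqrt(var_x * var_y)


def solve_coupling(
    config: GeneratorConfig, role: Role
) -> dict[ProcedureType, _TypeCoupling]:
    """Solve the within-type log-scale correlation so the pooled DAP–dose R²
    for ``role`` matches the configured target in expectation."""
    role = Role(role)
    target_r2 = config.coupling_r2.get(role, 0.0)
    target_r = math.sqrt(target_r2)  # positive coupling

    probs = dict(zip(_TYPES, config.type_probabilities))
    comps = []
    per_type: dict[ProcedureType, dict] = {}
    for ptype in _TYPES:
        weight = probs[ptype]
        if role is Role.ASSISTANT:
            weight *= config.assistant_presence.get(ptype, 0.0)
        dap = config.dap_models[ptype]
        dose = config.dose_models[(ptype, role)]
        mu_x, s_x = calibrate_lognormal(dap.mean, dap.sd)
        mu_y, s_y = calibrate_lognormal(dose.mean, dose.sd)
        mx, vx = _lognormal_moments(mu_x, s_x)
        my, vy = _lognormal_moments(mu_y, s_y)
        per_type[ptype] = dict(mu_x=mu_x, s_x=s_x, mu_y=mu_y, s_y=s_y)
        if weight > 0:
            comps.append(dict(w=weight, mx=mx, vx=vx, my=my, vy=vy, sx=s_x, sy=s_y))
    wsum = sum(c["w"] for c in comps)
    if wsum <= 0:
        raise CouplingError(f"role {role.value}: no procedures carry this role")
    for c in comps:
        c["w"] /= wsum

    if target_r2 == 0.0:
        rho = 0.0
    else:
        lo, hi = -0.999999, 0.999999
        r_hi = _pooled_corr(hi, comps)
        r_lo = _pooled_corr(lo, comps)
        if not (r_lo <= target_r <= r_hi):
            raise CouplingError(
                f"coupling target R²={target_r2} for role {role.value} infeasible: "
                f"attainable pooled correlation range is [{r_lo:.4f}, {r_hi:.4f}] "
                f"(R² up to {max(r_lo**2, r_hi**2):.4f}) given the DAP/dose marginals"
            )
        rho = brentq(lambda r: _pooled_corr(r, comps) - target_r, lo, hi, xtol=1e-12)

    out: dict[ProcedureType, _TypeCoupling] = {}
    for ptype in _TYPES:
        p = per_type[ptype]
        if p["s_x"] > 0 and p["s_y"] > 0:
            b = rho * p["s_y"] / p["s_x"]
            sd_eps = p["s_y"] * math.sqrt(max(0.0, 1.0 - rho * rho))
        else:
            b, sd_eps = 0.0, p["s_y"]
        a = p["mu_y"] - b * p["mu_x"]
        out[ptype] = _TypeCoupling(a=a, b=b, sd_eps=sd_eps, mu_y=p["mu_y"], sigma_y=p["s_y"])
    return out


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, n: int, low: float = 0.0,
    high: float = np.inf,
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a = (low - mean) / sd
    b = (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _sample_marginal(rng: np.random.Generator, model: DoseModel, n: int) -> np.ndarray:
    if model.sd == 0:
        return np.full(n, model.mean)
    if model.family == "gamma":
        shape = (model.mean / model.sd) ** 2
        scale = model.sd**2 / model.mean
        return rng.gamma(shape, scale, size=n)
    mu, sigma = calibrate_lognormal(model.mean, model.sd)
    return rng.lognormal(mu, sigma, size=n)


def _coupled_dose(
    rng: np.random.Generator,
    model: DoseModel,
    coupling: _TypeCoupling,
    dap: np.ndarray,
) -> np.ndarray:
    n = len(dap)
    if model.sd == 0:
        return np.full(n, model.mean)
    eps = rng.normal(0.0, coupling.sd_eps, size=n)
    if model.family == "gamma":
        # Gaussian-copula approximation: the log-linear latent drives the
        # rank structure; marginal mapped to the moment-matched gamma.
        from scipy.stats import gamma as gamma_dist, norm

        z = (coupling.b * (np.log(dap) if coupling.b else 0.0)) + eps
        latent = coupling.a + z
        u = norm.cdf((latent - coupling.mu_y) / max(coupling.sigma_y, 1e-12))
        shape = (model.mean / model.sd) ** 2
        scale = model.sd**2 / model.mean
        return gamma_dist.ppf(np.clip(u, 1e-12, 1 - 1e-12), shape, scale=scale)
    return np.exp(coupling.a + coupling.b * np.log(dap) + eps)


def generate_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Vectorized generation: one row per (procedure × operator).

    Same statistical model as :func:`generate` without materializing record
    objects; used for large calibration runs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_procedures
    probs = np.asarray(config.type_probabilities, dtype=float)
    probs = probs / probs.sum()
    type_codes = rng.choice(3, size=n, p=probs)

    tech = {f: np.empty(n) for f in _TECH_FIELDS}
    dap = np.empty(n)
    for code, ptype in enumerate(_TYPES):
        idx = np.flatnonzero(type_codes == code)
        if idx.size == 0:
            continue
        for fname in _TECH_FIELDS:
            mean, sd = config.technique_models[ptype][fname]
            tech[fname][idx] = _sample_truncnorm(rng, mean, sd, idx.size)
        dap[idx] = _sample_marginal(rng, config.dap_models[ptype], idx.size)

    coupling = {role: solve_coupling(config, role) for role in Role}

    prim_dose = np.empty(n)
    for code, ptype in enumerate(_TYPES):
        idx = np.flatnonzero(type_codes == code)
        if idx.size == 0:
            continue
        model = config.dose_models[(ptype, Role.PRIMARY)]
        prim_dose[idx] = _coupled_dose(rng, model, coupling[Role.PRIMARY][ptype], dap[idx])

    presence = np.array(
        [config.assistant_presence.get(t, 0.0) for t in _TYPES], dtype=float
    )
    has_assistant = rng.random(n) < presence[type_codes]
    asst_dose = np.full(n, np.nan)
    for code, ptype in enumerate(_TYPES):
        idx = np.flatnonzero((type_codes == code) & has_assistant)
        if idx.size == 0:
            continue
        model = config.dose_models[(ptype, Role.ASSISTANT)]
        asst_dose[idx] = _coupled_dose(rng, model, coupling[Role.ASSISTANT][ptype], dap[idx])

    prim_ids = rng.integers(1, config.n_primary_operators + 1, size=n)
    asst_ids = rng.integers(1, config.n_assistant_operators + 1, size=n)
    prim_age = np.empty(n)
    asst_age = np.empty(n)
    for code, ptype in enumerate(_TYPES):
        idx = np.flatnonzero(type_codes == code)
        if idx.size == 0:
            continue
        m, s = config.age_models[(ptype, Role.PRIMARY)]
        prim_age[idx] = _sample_truncnorm(rng, m, s, idx.size, low=18, high=80)
        m, s = config.age_models[(ptype, Role.ASSISTANT)]
        asst_age[idx] = _sample_truncnorm(rng, m, s, idx.size, low=18, high=80)

    male_prob = np.array(
        [config.assistant_male_prob.get(t, 1.0) for t in _TYPES], dtype=float
    )
    asst_male = rng.random(n) < male_prob[type_codes]

    weights = config.beam_weights
    if weights is None:
        weights = tuple(1.0 / len(config.beam_labels) for _ in config.beam_labels)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    fluoro_beam = rng.choice(len(config.beam_labels), size=n, p=w)
    acq_beam = rng.choice(len(config.beam_labels), size=n, p=w)

    rows = []
    type_values = np.array([t.value for t in _TYPES])
    for i in range(n):
        pid = f"SYN{i + 1:06d}"
        base = {
            "procedure_id": pid,
            "procedure_type": type_values[type_codes[i]],
            **{f: tech[f][i] for f in _TECH_FIELDS},
            "dap_gycm2": dap[i],
            "beam_fluoro": config.beam_labels[fluoro_beam[i]],
            "beam_acq": config.beam_labels[acq_beam[i]],
        }
        rows.append(
            {
                **base,
                "operator_id": f"P{prim_ids[i]}",
                "role": Role.PRIMARY.value,
                "age": float(np.clip(prim_age[i], 18, 80)),
                "sex": Sex.M.value,
                "epd_dose_usv": prim_dose[i],
            }
        )
        if has_assistant[i]:
            rows.append(
                {
                    **base,
                    "operator_id": f"A{asst_ids[i]}",
                    "role": Role.ASSISTANT.value,
                    "age": float(np.clip(asst_age[i], 18, 80)),
                    "sex": (Sex.M if asst_male[i] else Sex.F).value,
                    "epd_dose_usv": asst_dose[i],
                }
            )
    return pd.DataFrame(rows)


def generate(config: GeneratorConfig) -> list[ProcedureRecord]:
    """Generate synthetic :class:`ProcedureRecord` objects.

    Deterministic given ``config.seed``: identical seed and config yield
    byte-identical output.
    """
    frame = generate_frame(config)
    records: list[ProcedureRecord] = []
    for pid, group in frame.groupby("procedure_id", sort=False):
        first = group.iloc[0]
        operators = [
            OperatorDose(
                operator_id=row["operator_id"],
                role=Role(row["role"]),
                age=float(row["age"]),
                sex=Sex(row["sex"]),
                epd_dose_usv=float(row["epd_dose_usv"]),
            )
            for _, row in group.iterrows()
        ]
        records.append(
            ProcedureRecord(
                procedure_id=str(pid),
                procedure_type=ProcedureType(first["procedure_type"]),
                fluoro_time_min=float(first["fluoro_time_min"]),
                fluoro_kv=float(first["fluoro_kv"]),
                fluoro_ma=float(first["fluoro_ma"]),
                acq_kv=float(first["acq_kv"]),
                acq_ma=float(first["acq_ma"]),
                acq_time_s=float(first["acq_time_s"]),
                dap_gycm2=float(first["dap_gycm2"]),
                beam_directions=[
                    (str(first["beam_fluoro"]), "fluoroscopy"),
                    (str(first["beam_acq"]), "acquisition"),
                ],
                operator_doses=operators,
            )
        )
    return records
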