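"""Synthetic accident-record generator with planted stratified heterogeneity.

Records are drawn from a latent-mean model: each record falls in a spatial
zone (an isotropic Gaussian cluster of coordinates), draws a category for
every factor (optionally tilted by zone), and receives an outcome from a
noise model around

    mu = base_mean + effect_scale * ( sum_f a_f[code_f] + sum_(f,g) c[code_f, code_g] )

where the per-factor effects ``a`` are mean-centered under the category
probabilities and interaction cross-terms ``c`` are doubly centered.  Because
the effects are centered, the marginal outcome mean equals ``base_mean``
exactly in expectation, and the population q of a single additively acting
factor under Gaussian noise has the closed form of :func:`expected_q` —
which makes every detector testable against known ground truth.

Three noise models are available: Gaussian (continuous severity), Poisson
(counts), and a moment-matched small-support discrete distribution whose
mean and SD hit stated targets exactly; planted effects move its conditional
mean by exponential tilting, which preserves the support and the marginal
mean.

``make_preset`` ships ready-made study configurations, including a
calibration preset emulating the published summary statistics of the
Shenzhen 2014-2016 crash records (N = 3250, two severity groups with stated
outcome moments, 17 coded factors, 5 spatial zones).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, nnls

from .records import AccidentTable, FactorCoding, default_coding

__all__ = [
    "FactorSpec",
    "InteractionSpec",
    "ZoneLayout",
    "GaussianNoise",
    "PoissonNoise",
    "MomentMatchedDiscrete",
    "OutcomeModel",
    "SynthConfig",
    "generate",
    "expected_q",
    "make_preset",
    "planted_q_config",
    "solve_support_probs",
]

_CENTER_TOL = 1e-8


def _center(p: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Shift effects so their probability-weighted mean is zero."""
    return a - float(np.dot(p, a))


@dataclass(frozen=True)
class FactorSpec:
    """One categorical factor of the generator.

    ``p`` are the category probabilities (a simplex over ``codes``), ``a``
    the outcome-mean shifts per category, mean-centered under ``p``.  A
    factor may instead mirror the spatial zone of the record
    (``from_zone=True``), in which case ``p`` must equal the zone
    probabilities and ``a`` indexes zones.  ``zone_tilt`` optionally gives
    per-zone multiplicative probability weights (rows: zones) to induce
    factor-zone dependence.
    """

    name: str
    codes: tuple[int, ...]
    p: tuple[float, ...]
    a: tuple[float, ...]
    zone_tilt: tuple[tuple[float, ...], ...] | None = None
    from_zone: bool = False

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        a = np.asarray(self.a, dtype=float)
        if not (len(self.codes) == len(p) == len(a)):
            raise ValueError(f"factor {self.name!r}: codes/p/a lengths differ")
        if abs(p.sum() - 1.0) > _CENTER_TOL or np.any(p < 0):
            raise ValueError(f"factor {self.name!r}: p must be a simplex")
        if abs(float(np.dot(p, a))) > _CENTER_TOL:
            raise ValueError(
                f"factor {self.name!r}: effects not centered (sum p_h a_h != 0)"
            )
        if self.zone_tilt is not None:
            t = np.asarray(self.zone_tilt, dtype=float)
            if t.ndim != 2 or t.shape[1] != len(self.codes) or np.any(t < 0):
                raise ValueError(f"factor {self.name!r}: malformed zone_tilt")


@dataclass(frozen=True)
class InteractionSpec:
    """A planted cross-term between two factors.

    ``c[h, k]`` is added to the latent mean when the record falls in category
    ``h`` of ``name_a`` and ``k`` of ``name_b``; it must be doubly centered
    under the two factors' category probabilities so that it contributes no
    marginal (single-factor) effect.
    """

    name_a: str
    name_b: str
    c: tuple[tuple[float, ...], ...]


@dataclass(frozen=True)
class ZoneLayout:
    """Spatial cluster layout: one isotropic Gaussian cloud per zone."""

    centers: tuple[tuple[float, float], ...]    # (lon, lat) degrees
    spreads: tuple[float, ...]                  # SD in degrees, per zone
    probs: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.centers) == len(self.spreads) == len(self.probs)):
            raise ValueError("zone layout arrays must align")
        if abs(sum(self.probs) - 1.0) > _CENTER_TOL:
            raise ValueError("zone probabilities must sum to 1")

    @property
    def n_zones(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class GaussianNoise:
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("gaussian sigma must be > 0")


@dataclass(frozen=True)
class PoissonNoise:
    pass


@dataclass(frozen=True)
class MomentMatchedDiscrete:
    """Small-support discrete distribution matching a target mean and SD.

    The base probabilities are solved from the moment system on ``support``;
    an incompatible (support, mean, sd) combination raises at construction.
    Conditional means planted by factor effects are realised by exponential
    tilting of the base probabilities.
    """

    support: tuple[float, ...]
    mean: float
    sd: float

    def __post_init__(self):
        solve_support_probs(self.support, self.mean, self.sd)  # feasibility

    def base_probs(self) -> np.ndarray:
        return solve_support_probs(self.support, self.mean, self.sd)


NoiseModel = GaussianNoise | PoissonNoise | MomentMatchedDiscrete


def solve_support_probs(support: Sequence[float], mean: float,
                        sd: float) -> np.ndarray:
    """Probabilities on ``support`` with the requested mean and SD.

    Solves the non-negative least-squares moment system; raises
    ``ValueError`` naming the infeasible constraint when no distribution on
    the support attains the moments.
    """
    x = np.asarray(support, dtype=float)
    if len(x) < 2 or len(np.unique(x)) != len(x):
        raise ValueError("support needs >= 2 distinct points")
    target = np.array([1.0, mean, sd**2 + mean**2])
    design = np.vstack([np.ones_like(x), x, x**2])
    probs, residual = nnls(design, target)
    if residual > 1e-8:
        raise ValueError(
            f"moment matching infeasible: no distribution on support "
            f"{tuple(x)} has mean {mean} and SD {sd} "
            f"(moment-system residual {residual:.3g})"
        )
    return probs / probs.sum()


def _tilted_probs(support: np.ndarray, base: np.ndarray,
                  target_mean: float) -> np.ndarray:
    """Exponentially tilt ``base`` on ``support`` to the target mean."""
    m0 = float(np.dot(base, support))
    if abs(target_mean - m0) < 1e-12:
        return base

    def g(theta):
        w = base * np.exp(theta * (support - support.mean()))
        return float(np.dot(w, support) / w.sum()) - target_mean

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if g(lo) < 0 < g(hi):
            break
        lo *= 2.0
        hi *= 2.0
    theta = brentq(g, lo, hi, xtol=1e-12)
    w = base * np.exp(theta * (support - support.mean()))
    return w / w.sum()


@dataclass(frozen=True)
class OutcomeModel:
    """Noise model + baseline for one outcome column."""

    noise: NoiseModel
    base_mean: float
    effect_scale: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Full recipe for one synthetic accident table.

    ``outcome`` selects which column the latent model drives: a single
    outcome ("fatalities" or "injuries", the other column is zero) or
    ``"both"``, in which case records are assigned to the fatal group with
    probability ``group1_fraction`` and each group's outcome is drawn from
    its own :class:`OutcomeModel`.
    """

    n_records: int
    zones: ZoneLayout
    factors: tuple[FactorSpec, ...]
    models: Mapping[str, OutcomeModel]
    interactions: tuple[InteractionSpec, ...] = ()
    outcome: str = "fatalities"
    group1_fraction: float = 0.3
    years: tuple[int, int] = (2014, 2016)
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.outcome not in ("fatalities", "injuries", "both"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        needed = (["fatalities", "injuries"] if self.outcome == "both"
                  else [self.outcome])
        for name in needed:
            if name not in self.models:
                raise ValueError(f"missing OutcomeModel for {name!r}")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")
        lookup = {f.name: f for f in self.factors}
        for spec in self.interactions:
            fa = lookup.get(spec.name_a)
            fb = lookup.get(spec.name_b)
            if fa is None or fb is None:
                raise ValueError("interaction references unknown factor")
            c = np.asarray(spec.c, dtype=float)
            if c.shape != (len(fa.codes), len(fb.codes)):
                raise ValueError("interaction matrix shape mismatch")
            pa = np.asarray(fa.p)
            pb = np.asarray(fb.p)
            if (np.max(np.abs(pa @ c)) > 1e-7
                    or np.max(np.abs(c @ pb)) > 1e-7):
                raise ValueError(
                    f"interaction {spec.name_a}x{spec.name_b} not doubly centered"
                )

    # -- JSON round trip -------------------------------------------------
    def to_json(self, path=None) -> str:
        def encode_noise(nm):
            d = asdict(nm)
            d["kind"] = type(nm).__name__
            return d

        payload = {
            "n_records": self.n_records,
            "zones": asdict(self.zones),
            "factors": [asdict(f) for f in self.factors],
            "interactions": [asdict(i) for i in self.interactions],
            "models": {
                k: {"noise": encode_noise(m.noise), "base_mean": m.base_mean,
                    "effect_scale": m.effect_scale}
                for k, m in self.models.items()
            },
            "outcome": self.outcome,
            "group1_fraction": self.group1_fraction,
            "years": list(self.years),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_json(source) -> "SynthConfig":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)

        def decode_noise(d):
            kind = d.pop("kind")
            cls = {"GaussianNoise": GaussianNoise, "PoissonNoise": PoissonNoise,
                   "MomentMatchedDiscrete": MomentMatchedDiscrete}[kind]
            if kind == "MomentMatchedDiscrete":
                d["support"] = tuple(d["support"])
            return cls(**d)

        def tup2(rows):
            return tuple(tuple(r) for r in rows)

        zones = ZoneLayout(
            centers=tup2(payload["zones"]["centers"]),
            spreads=tuple(payload["zones"]["spreads"]),
            probs=tuple(payload["zones"]["probs"]),
        )
        factors = tuple(
            FactorSpec(
                name=f["name"], codes=tuple(f["codes"]), p=tuple(f["p"]),
                a=tuple(f["a"]),
                zone_tilt=tup2(f["zone_tilt"]) if f.get("zone_tilt") else None,
                from_zone=f.get("from_zone", False),
            )
            for f in payload["factors"]
        )
        interactions = tuple(
            InteractionSpec(i["name_a"], i["name_b"], tup2(i["c"]))
            for i in payload["interactions"]
        )
        models = {
            k: OutcomeModel(noise=decode_noise(dict(m["noise"])),
                            base_mean=m["base_mean"],
                            effect_scale=m["effect_scale"])
            for k, m in payload["models"].items()
        }
        return SynthConfig(
            n_records=payload["n_records"], zones=zones, factors=factors,
            models=models, interactions=interactions,
            outcome=payload["outcome"],
            group1_fraction=payload["group1_fraction"],
            years=tuple(payload["years"]), seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_codes(config: SynthConfig, zone: np.ndarray,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-factor arrays of category INDICES (not codes)."""
    n = config.n_records
    out: dict[str, np.ndarray] = {}
    for f in config.factors:
        k = len(f.codes)
        if f.from_zone:
            out[f.name] = zone.copy()
        elif f.zone_tilt is not None:
            tilt = np.asarray(f.zone_tilt, dtype=float)
            p = np.asarray(f.p, dtype=float)
            idx = np.empty(n, dtype=np.intp)
            for z in range(config.zones.n_zones):
                members = np.flatnonzero(zone == z)
                if len(members) == 0:
                    continue
                pz = p * tilt[z]
                pz = pz / pz.sum()
                idx[members] = rng.choice(k, size=len(members), p=pz)
            out[f.name] = idx
        else:
            out[f.name] = rng.choice(k, size=n, p=np.asarray(f.p, dtype=float))
    return out


def _latent_effect(config: SynthConfig,
                   indices: Mapping[str, np.ndarray]) -> np.ndarray:
    e = np.zeros(config.n_records)
    for f in config.factors:
        e += np.asarray(f.a, dtype=float)[indices[f.name]]
    for spec in config.interactions:
        c = np.asarray(spec.c, dtype=float)
        e += c[indices[spec.name_a], indices[spec.name_b]]
    return e


def _draw_outcome(model: OutcomeModel, effect: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    mu = model.base_mean + model.effect_scale * effect
    noise = model.noise
    if isinstance(noise, GaussianNoise):
        return np.clip(mu + rng.normal(0.0, noise.sigma, size=len(mu)), 0.0, None)
    if isinstance(noise, PoissonNoise):
        return rng.poisson(np.clip(mu, 0.0, None)).astype(float)
    if isinstance(noise, MomentMatchedDiscrete):
        support = np.asarray(noise.support, dtype=float)
        base = noise.base_probs()
        margin = 0.02 * (support.max() - support.min())
        mu = np.clip(mu, support.min() + margin, support.max() - margin)
        out = np.empty(len(mu))
        keys = np.round(mu, 9)
        for key in np.unique(keys):
            members = np.flatnonzero(keys == key)
            probs = _tilted_probs(support, base, float(key))
            out[members] = rng.choice(support, size=len(members), p=probs)
        return out
    raise TypeError(f"unknown noise model {noise!r}")


def _build_coding(config: SynthConfig) -> dict[str, FactorCoding]:
    known = default_coding()
    coding = {}
    for f in config.factors:
        if f.name in known and set(f.codes) <= known[f.name].codes:
            coding[f.name] = known[f.name]
        else:
            coding[f.name] = FactorCoding(
                f.name, tuple((c, f"category {c}") for c in f.codes)
            )
    return coding


def generate(config: SynthConfig, seed: int | None = None) -> AccidentTable:
    """Draw a full accident table from the configured generative model.

    Reproducible: the same ``seed`` (or ``config.seed`` when none is given)
    yields an identical table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_records
    zl = config.zones
    zone = rng.choice(zl.n_zones, size=n, p=np.asarray(zl.probs, dtype=float))
    centers = np.asarray(zl.centers, dtype=float)
    spreads = np.asarray(zl.spreads, dtype=float)
    lon = centers[zone, 0] + rng.normal(0.0, 1.0, n) * spreads[zone]
    lat = centers[zone, 1] + rng.normal(0.0, 1.0, n) * spreads[zone]
    year = rng.integers(config.years[0], config.years[1] + 1, size=n)

    indices = _draw_codes(config, zone, rng)
    effect = _latent_effect(config, indices)

    fat = np.zeros(n)
    inj = np.zeros(n)
    if config.outcome == "both":
        in_g1 = rng.random(n) < config.group1_fraction
        if in_g1.any():
            fat[in_g1] = _draw_outcome(config.models["fatalities"],
                                       effect[in_g1], rng)
        if (~in_g1).any():
            inj[~in_g1] = _draw_outcome(config.models["injuries"],
                                        effect[~in_g1], rng)
    elif config.outcome == "fatalities":
        fat = _draw_outcome(config.models["fatalities"], effect, rng)
    else:
        inj = _draw_outcome(config.models["injuries"], effect, rng)

    data = {
        "record_id": [f"r{i:05d}" for i in range(n)],
        "lon": lon,
        "lat": lat,
        "year": year,
        "fatalities": fat,
        "injuries": inj,
    }
    for f in config.factors:
        codes = np.asarray(f.codes)[indices[f.name]]
        data[f.name] = codes
    return AccidentTable(pd.DataFrame(data), _build_coding(config))


def expected_q(spec: FactorSpec, noise_variance: float) -> float:
    """Population q of a single additively acting factor under Gaussian noise.

    With centered effects the between-strata variance is ``sum_h p_h a_h^2``
    and the within-strata variance is the noise variance, so

        q = sum_h p_h a_h^2 / (sum_h p_h a_h^2 + sigma^2).
    """
    if noise_variance <= 0:
        raise ValueError("noise_variance must be > 0")
    p = np.asarray(spec.p, dtype=float)
    a = np.asarray(spec.a, dtype=float)
    between = float(np.dot(p, a**2))
    return between / (between + noise_variance)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _decay_probs(k: int, r: float = 0.85) -> tuple[float, ...]:
    w = r ** np.arange(k)
    return tuple(w / w.sum())


def _ramp_effects(p: Sequence[float], amplitude: float) -> tuple[float, ...]:
    """Monotone centered effect ramp with SD ``amplitude`` under ``p``.

    Normalising to unit variance before scaling makes the planted
    between-strata variance simply ``amplitude**2``, so per-factor q targets
    translate directly into amplitudes.
    """
    p = np.asarray(p, dtype=float)
    k = len(p)
    raw = np.arange(k, dtype=float) / max(k - 1, 1)
    raw = _center(p, raw)
    sd = math.sqrt(float(np.dot(p, raw**2)))
    return tuple(amplitude * raw / sd)


_SHENZHEN_ZONES = ZoneLayout(
    centers=((114.06, 22.55), (113.88, 22.57), (114.05, 22.68),
             (114.25, 22.72), (114.50, 22.60)),
    spreads=(0.035, 0.04, 0.045, 0.05, 0.04),
    probs=(0.35, 0.20, 0.20, 0.15, 0.10),
)


def _shenzhen_factor(name: str, coding: Mapping[str, FactorCoding],
                     amplitude: float = 0.0, r: float = 0.85,
                     tilt_strength: float = 0.0,
                     n_zones: int = 5) -> FactorSpec:
    codes = tuple(c for c, _ in coding[name].categories)
    p = _decay_probs(len(codes), r)
    a = _ramp_effects(p, amplitude) if amplitude else tuple(0.0 for _ in codes)
    tilt = None
    if tilt_strength:
        k = len(codes)
        tilt = tuple(
            tuple(1.0 + tilt_strength * math.cos(2 * math.pi * (i + z) / k)
                  for i in range(k))
            for z in range(n_zones)
        )
    return FactorSpec(name=name, codes=codes, p=p, a=a, zone_tilt=tilt)


def _shenzhen_like() -> SynthConfig:
    coding = default_coding()
    zones_p = np.asarray(_SHENZHEN_ZONES.probs)
    zone_raw = _center(zones_p, np.array([-1.0, 0.2, -0.2, 1.0, 0.5]))
    zone_raw /= math.sqrt(float(zones_p @ zone_raw**2))
    zone_effects = tuple(0.4 * zone_raw)
    # relative amplitudes: violation factors strongest, then road geometry,
    # then environment; amplitudes are effect SDs in units of effect_scale
    factors = [
        FactorSpec(name="zones", codes=(1, 2, 3, 4, 5), p=_SHENZHEN_ZONES.probs,
                   a=zone_effects, from_zone=True),
        _shenzhen_factor("seasons", coding, amplitude=0.2, r=0.95),
        _shenzhen_factor("day_of_week", coding, r=0.98),
        _shenzhen_factor("time_interval", coding, amplitude=0.25, r=0.9),
        _shenzhen_factor("road_type", coding, amplitude=0.6, r=0.85),
        _shenzhen_factor("road_line_style", coding, amplitude=0.4, r=0.7),
        _shenzhen_factor("road_section_type", coding, amplitude=0.4, r=0.7),
        _shenzhen_factor("pavement_material", coding, amplitude=0.2, r=0.5),
        _shenzhen_factor("pavement_condition", coding, amplitude=0.2, r=0.5),
        _shenzhen_factor("roadside_protection", coding, amplitude=0.25, r=0.8),
        _shenzhen_factor("traffic_sign", coding, r=0.4),
        _shenzhen_factor("lighting_condition", coding, amplitude=0.25, r=0.6),
        _shenzhen_factor("weather", coding, r=0.55, tilt_strength=0.4),
        _shenzhen_factor("topography", coding, amplitude=0.3, r=0.5),
        _shenzhen_factor("primary_cause", coding, amplitude=1.0, r=0.88,
                         tilt_strength=0.3),
        _shenzhen_factor("whether_illegal", coding, amplitude=0.2, r=0.25),
        _shenzhen_factor("responsible_party", coding, amplitude=0.8, r=0.8),
    ]
    models = {
        # Printed SD 0.48/0.301 is infeasible for positive integer counts, so
        # group-1 severity uses a positive 3-point support matching the
        # printed moments exactly (see docs/methods.md).  effect_scale is the
        # between-strata SD contributed by a unit-amplitude factor.
        "fatalities": OutcomeModel(
            noise=MomentMatchedDiscrete(support=(0.25, 0.5, 1.0),
                                        mean=0.48, sd=0.301),
            base_mean=0.48, effect_scale=0.095),
        "injuries": OutcomeModel(
            noise=MomentMatchedDiscrete(support=(1.0, 2.0, 5.0),
                                        mean=1.41, sd=1.055),
            base_mean=1.41, effect_scale=0.14),
    }
    return SynthConfig(
        n_records=3250, zones=_SHENZHEN_ZONES, factors=tuple(factors),
        models=models, outcome="both", group1_fraction=0.30,
        years=(2014, 2016), seed=0,
    )


def _generic_factor(name: str, k: int, amplitude: float = 0.0,
                    uniform: bool = True, r: float = 0.85) -> FactorSpec:
    codes = tuple(range(1, k + 1))
    p = tuple(1.0 / k for _ in codes) if uniform else _decay_probs(k, r)
    a = _ramp_effects(p, amplitude) if amplitude else tuple(0.0 for _ in codes)
    return FactorSpec(name=name, codes=codes, p=p, a=a)


def _null_preset() -> SynthConfig:
    zones = ZoneLayout(centers=((0.0, 0.0), (0.3, 0.1), (0.1, 0.4)),
                       spreads=(0.05, 0.05, 0.05), probs=(0.4, 0.35, 0.25))
    factors = tuple(
        _generic_factor(name, k)
        for name, k in [("factor_a", 4), ("factor_b", 5),
                        ("factor_c", 3), ("factor_d", 7)]
    )
    models = {"fatalities": OutcomeModel(GaussianNoise(1.0), base_mean=1.0)}
    return SynthConfig(n_records=1000, zones=zones, factors=factors,
                       models=models, outcome="fatalities", seed=0)


def _interaction_demo() -> SynthConfig:
    zones = ZoneLayout(centers=((0.0, 0.0), (0.5, 0.5)),
                       spreads=(0.05, 0.05), probs=(0.5, 0.5))
    fa = _generic_factor("factor_a", 3)
    fb = _generic_factor("factor_b", 3)
    # doubly centered (uniform p) diagonal cross-term: joint cells matter,
    # marginals carry nothing
    c = 0.6 * (3.0 * np.eye(3) - 1.0)
    spec = InteractionSpec("factor_a", "factor_b",
                           tuple(tuple(row) for row in c))
    models = {"fatalities": OutcomeModel(GaussianNoise(1.0), base_mean=5.0)}
    return SynthConfig(n_records=2000, zones=zones, factors=(fa, fb),
                       models=models, interactions=(spec,),
                       outcome="fatalities", seed=0)


def _spatial_demo() -> SynthConfig:
    zones = ZoneLayout(
        centers=((0.0, 0.0), (0.4, 0.0), (0.0, 0.4), (0.4, 0.4), (0.2, 0.2)),
        spreads=(0.02, 0.02, 0.02, 0.02, 0.02),
        probs=(0.2, 0.2, 0.2, 0.2, 0.2),
    )
    p = zones.probs
    a = tuple(_center(np.asarray(p), 2.0 * np.array([-1.0, -0.5, 0.0, 0.5, 1.0])))
    zf = FactorSpec(name="zones", codes=(1, 2, 3, 4, 5), p=p, a=a, from_zone=True)
    models = {"fatalities": OutcomeModel(GaussianNoise(0.5), base_mean=5.0)}
    return SynthConfig(n_records=800, zones=zones, factors=(zf,),
                       models=models, outcome="fatalities", seed=0)


_PRESETS = {
    "shenzhen_like": _shenzhen_like,
    "null": _null_preset,
    "interaction_demo": _interaction_demo,
    "spatial_demo": _spatial_demo,
}


def make_preset(name: str) -> SynthConfig:
    """Ready-made generator configurations.

    * ``shenzhen_like`` — N = 3250, 5 spatial zones, the full 17-factor
      coding, two severity groups with moment-matched outcomes (group-1
      severity mean 0.48 / SD 0.301, group-2 injuries mean 1.41 / SD 1.055)
      and modest planted effects on the violation-related factors.
    * ``null`` — no planted structure at all; every factor q should be
      statistically indistinguishable from zero.
    * ``interaction_demo`` — two individually powerless factors with a strong
      planted cross-term (nonlinear enhancement).
    * ``spatial_demo`` — tight spatial clusters with zone-shifted outcome
      means, for exercising the Moran's I check.
    """
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None


def planted_q_config(q_star: float, n_records: int, n_categories: int = 5,
                     sigma: float = 1.0, seed: int = 0) -> SynthConfig:
    """Single-factor configuration whose population q equals ``q_star``.

    The factor's effect amplitude is solved from the closed form of
    :func:`expected_q`: between-variance = sigma^2 * q* / (1 - q*).
    """
    if not (0.0 <= q_star < 1.0):
        raise ValueError("q_star must be in [0, 1)")
    k = n_categories
    p = np.full(k, 1.0 / k)
    raw = 2 * np.arange(k) / (k - 1) - 1.0
    raw = _center(p, raw)
    base_var = float(np.dot(p, raw**2))
    target = sigma**2 * q_star / (1.0 - q_star) if q_star > 0 else 0.0
    scale = math.sqrt(target / base_var) if target > 0 else 0.0
    factor = FactorSpec(name="planted", codes=tuple(range(1, k + 1)),
                        p=tuple(p), a=tuple(scale * raw))
    zones = ZoneLayout(centers=((0.0, 0.0), (0.5, 0.5)),
                       spreads=(0.1, 0.1), probs=(0.5, 0.5))
    models = {"fatalities": OutcomeModel(GaussianNoise(sigma), base_mean=5.0)}
    return SynthConfig(n_records=n_records, zones=zones, factors=(factor,),
                       models=models, outcome="fatalities", seed=seed)
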