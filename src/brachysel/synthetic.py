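"""Synthetic gynecologic-brachytherapy cohorts and analytic test phantoms.

No public structure-set database exists for this task, so the pipeline is
exercised on generated anatomy with the statistical structure the analysis
assumes: an ellipsoidal HR-CTV whose size and lateral offset from the tandem
axis drive applicator choice through a logistic label model centred on the
clinical rules of thumb (interstitial needles indicated above ~25 mm lateral
extent or ~30 cm^3 volume); ellipsoidal bladder, rectum and sigmoid placed
anterior, posterior and supero-posterior of the target with sampled gaps;
and dosimetric records drawn to match configured plan-quality stratum
proportions, with sub-optimal strata enriched among fractions whose label
disagrees with their geometry.

The default configuration reproduces the composition of the institutional
cohort the method was developed on: 233 fractions, 147 intracavitary vs 86
hybrid interstitial, and plan-quality strata in 134:32:67 proportion.

``make_analytic_phantom`` builds exact contour stacks of simple solids
(sphere, ellipsoid, cylinder, hemisphere, slab, facing cube pair) for which
every geometry metric has a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .quality_weighting import EMBRACE_METRICS, ConstraintConfig
from .structure_io import (
    ApplicatorClass,
    ApplicatorFrame,
    PlanarContour,
    StructureSet,
    write_structure_set,
)

__all__ = [
    "CohortConfig",
    "SyntheticFraction",
    "generate_cohort",
    "make_analytic_phantom",
    "label_model_oracle_accuracy",
    "write_cohort",
    "load_cohort_manifest",
]

_CANONICAL_FRAME = dict(
    tandem_point=(0.0, 0.0, 0.0),
    tandem_dir=(0.0, 0.0, 1.0),
    ring_point=(0.0, 0.0, 0.0),
    ring_normal=(0.0, 0.0, 1.0),
)


@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Geometry scales are mm. HR-CTV semi-axes are lognormal with the given
    medians and log-scale sigma; the lateral centroid offset from the tandem
    axis is half-normal. The label model is Bernoulli with
    ``logit = b0 + b_lat * (true max lateral extent - 25 mm)
    + b_vol * (true volume - 30 cm^3)``, rebalanced by rejection to the
    configured class counts.
    """

    n_fractions: int = 233
    n_ic: int = 147
    n_is: int = 86
    hrctv_semi_axis_medians: tuple[float, float, float] = (22.0, 18.0, 28.0)
    hrctv_sigma_log: float = 0.25
    lateral_offset_sigma: float = 6.0  # half-normal, mm
    beta0: float = -0.5
    beta_lat: float = 0.25  # per mm
    beta_vol: float = 0.12  # per cm^3
    oar_gap_range: tuple[float, float] = (3.0, 15.0)
    #: plan-quality stratum probabilities for weights (1.0, 0.5, 0.25)
    stratum_probs: tuple[float, float, float] = (134 / 233, 32 / 233, 67 / 233)
    #: probability that a low-quality stratum migrates onto a fraction whose
    #: label disagrees with its geometry
    mismatch_enrichment: float = 0.5
    slice_spacing: float = 2.0
    n_vertices: int = 96
    rejection_cap: int = 40  # multiples of n_fractions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ic + self.n_is != self.n_fractions:
            raise ValueError("class counts must sum to n_fractions")
        if abs(sum(self.stratum_probs) - 1.0) > 1e-9:
            raise ValueError("stratum probabilities must sum to 1")
        if min(self.hrctv_semi_axis_medians) <= 0 or self.lateral_offset_sigma <= 0:
            raise ValueError("scale parameters must be > 0")


@dataclass
class SyntheticFraction:
    """One generated treatment fraction with its generative ground truth."""

    fraction_id: int
    structure_set: StructureSet
    frame: ApplicatorFrame
    record: dict[str, float]
    label: str
    true_volume: float  # cm^3
    true_lat_max: float  # mm
    stratum_weight: float


# ---------------------------------------------------------------------------
# contour primitives


def _ellipse_contour(
    z: float, cx: float, cy: float, a: float, b: float, n: int
) -> PlanarContour:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    verts = np.column_stack([cx + a * np.cos(th), cy + b * np.sin(th)])
    return PlanarContour(z=z, vertices=verts)


def _box_contour(z: float, cx: float, cy: float, hx: float, hy: float) -> PlanarContour:
    verts = np.array(
        [[cx - hx, cy - hy], [cx + hx, cy - hy], [cx + hx, cy + hy], [cx - hx, cy + hy]]
    )
    return PlanarContour(z=z, vertices=verts)


def _slice_positions(z0: float, z1: float, h: float) -> np.ndarray:
    """Midpoint slice planes covering [z0, z1] at spacing h (midpoint-rule
    slabs, so stacked-slab volumes match the analytic integral closely)."""
    n = max(int(round((z1 - z0) / h)), 1)
    return z0 + (np.arange(n) + 0.5) * (z1 - z0) / n


def _ellipsoid_contours(
    center: Sequence[float],
    semi_axes: Sequence[float],
    h: float,
    n_vertices: int,
) -> list[PlanarContour]:
    cx, cy, cz = center
    a, b, c = semi_axes
    contours = []
    for z in _slice_positions(cz - c, cz + c, h):
        t = 1.0 - ((z - cz) / c) ** 2
        if t <= 0:
            continue
        r = math.sqrt(t)
        contours.append(_ellipse_contour(z, cx, cy, a * r, b * r, n_vertices))
    return contours


# ---------------------------------------------------------------------------
# analytic phantoms


def make_analytic_phantom(
    kind: str,
    slice_spacing: float = 2.0,
    n_vertices: int = 96,
    **params,
) -> tuple[StructureSet, ApplicatorFrame]:
    """Exact contour stack of a named solid in the canonical applicator frame
    (tandem axis = z axis through the origin, ring plane = z = 0).

    Kinds and parameters (mm):

    - ``sphere``: ``radius``, optional ``center``
    - ``ellipsoid``: ``semi_axes`` (a, b, c), optional ``center``
    - ``cylinder``: ``radius``, ``height``, optional ``center`` (of the base)
    - ``hemisphere``: ``radius`` — flat face on the ring plane, dome superior
    - ``slab``: ``size`` (lx, ly), ``thickness`` — resting on the ring plane
    - ``two_cubes``: ``size``, ``gap`` — an HR-CTV cube and a rectum cube
      facing it across ``gap`` along y
    """
    frame = ApplicatorFrame(**_CANONICAL_FRAME)
    h, nv = slice_spacing, n_vertices
    structures: dict[str, list[PlanarContour]]

    if kind == "sphere":
        r = float(params["radius"])
        _check_positive(r)
        center = params.get("center", (0.0, 0.0, 0.0))
        structures = {"HR-CTV": _ellipsoid_contours(center, (r, r, r), h, nv)}
    elif kind == "ellipsoid":
        a, b, c = (float(v) for v in params["semi_axes"])
        _check_positive(min(a, b, c))
        center = params.get("center", (0.0, 0.0, 0.0))
        structures = {"HR-CTV": _ellipsoid_contours(center, (a, b, c), h, nv)}
    elif kind == "cylinder":
        r, height = float(params["radius"]), float(params["height"])
        _check_positive(min(r, height))
        cx, cy, cz = params.get("center", (0.0, 0.0, 0.0))
        contours = [
            _ellipse_contour(z, cx, cy, r, r, nv)
            for z in _slice_positions(cz, cz + height, h)
        ]
        structures = {"HR-CTV": contours}
    elif kind == "hemisphere":
        r = float(params["radius"])
        _check_positive(r)
        contours = []
        for z in _slice_positions(0.0, r, h):
            rho = math.sqrt(max(r**2 - z**2, 0.0))
            if rho > 0:
                contours.append(_ellipse_contour(z, 0.0, 0.0, rho, rho, nv))
        structures = {"HR-CTV": contours}
    elif kind == "slab":
        lx, ly = (float(v) for v in params["size"])
        t = float(params["thickness"])
        _check_positive(min(lx, ly, t))
        contours = [
            _box_contour(z, 0.0, 0.0, lx / 2, ly / 2)
            for z in _slice_positions(0.0, t, h)
        ]
        structures = {"HR-CTV": contours}
    elif kind == "two_cubes":
        size, gap = float(params["size"]), float(params["gap"])
        _check_positive(min(size, gap))
        zs = _slice_positions(0.0, size, h)
        hs = size / 2
        # rectum cube center sits a face gap of `gap` past the HR-CTV far
        # face: centers at y = 0 and y = size + gap
        structures = {
            "HR-CTV": [_box_contour(z, 0.0, 0.0, hs, hs) for z in zs],
            "rectum": [_box_contour(z, 0.0, size + gap, hs, hs) for z in zs],
        }
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    return StructureSet(structures=structures, frame_of_reference="phantom"), frame


def _check_positive(v: float) -> None:
    if v <= 0:
        raise ValueError("phantom dimensions must be positive")


# ---------------------------------------------------------------------------
# cohort generation


def _true_lat_max(
    off: np.ndarray, a: float, b: float, n_theta: int = 720
) -> float:
    """Greatest perpendicular distance from the tandem (z) axis to the
    surface of an ellipsoid laterally offset by ``off`` — attained on the
    equatorial slice."""
    th = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    x = off[0] + a * np.cos(th)
    y = off[1] + b * np.sin(th)
    return float(np.max(np.hypot(x, y)))


_OAR_SHAPES = {  # median semi-axes, mm
    "bladder": (30.0, 24.0, 28.0),
    "rectum": (14.0, 14.0, 30.0),
    "sigmoid": (13.0, 13.0, 24.0),
}
_OAR_DIRECTIONS = {  # placement direction from the HR-CTV center (LPS)
    "bladder": np.array([0.0, -1.0, 0.0]),  # anterior
    "rectum": np.array([0.0, 1.0, 0.0]),  # posterior
    "sigmoid": np.array([0.0, 1.0, 1.0]) / math.sqrt(2.0),  # supero-posterior
}


def _directional_radius(semi_axes: Sequence[float], direction: np.ndarray) -> float:
    """Support-like radius of an ellipsoid along a unit direction."""
    a = np.asarray(semi_axes, dtype=float)
    return float(1.0 / math.sqrt(np.sum((direction / a) ** 2)))


def _sample_geometry(rng: np.random.Generator, cfg: CohortConfig) -> dict:
    med = np.asarray(cfg.hrctv_semi_axis_medians)
    semi = med * np.exp(rng.normal(0.0, cfg.hrctv_sigma_log, size=3))
    off_mag = abs(rng.normal(0.0, cfg.lateral_offset_sigma))
    ang = rng.uniform(0.0, 2.0 * np.pi)
    off = np.array([off_mag * math.cos(ang), off_mag * math.sin(ang)])
    gaps = {o: rng.uniform(*cfg.oar_gap_range) for o in _OAR_SHAPES}
    oar_semi = {
        o: np.asarray(s) * np.exp(rng.normal(0.0, 0.12, size=3))
        for o, s in _OAR_SHAPES.items()
    }
    return {"semi": semi, "off": off, "gaps": gaps, "oar_semi": oar_semi}


def _build_fraction_geometry(
    geom: dict, cfg: CohortConfig
) -> tuple[StructureSet, ApplicatorFrame, float, float]:
    a, b, c = geom["semi"]
    off = geom["off"]
    center = np.array([off[0], off[1], c])  # base of the target on the ring plane
    structures = {
        "HR-CTV": _ellipsoid_contours(center, (a, b, c), cfg.slice_spacing,
                                      cfg.n_vertices)
    }
    for oar, direction in _OAR_DIRECTIONS.items():
        semi_o = geom["oar_semi"][oar]
        dist = (
            _directional_radius((a, b, c), direction)
            + geom["gaps"][oar]
            + _directional_radius(semi_o, direction)
        )
        oc = center + direction * dist
        structures[oar] = _ellipsoid_contours(oc, tuple(semi_o), cfg.slice_spacing,
                                              cfg.n_vertices)
    struct = StructureSet(structures=structures, frame_of_reference="synthetic")
    frame = ApplicatorFrame(**_CANONICAL_FRAME)
    true_vol = 4.0 / 3.0 * math.pi * a * b * c / 1000.0
    true_lat = _true_lat_max(off, a, b)
    return struct, frame, true_vol, true_lat


def _label_probability(true_lat: float, true_vol: float, cfg: CohortConfig) -> float:
    logit = (
        cfg.beta0
        + cfg.beta_lat * (true_lat - 25.0)
        + cfg.beta_vol * (true_vol - 30.0)
    )
    return 1.0 / (1.0 + math.exp(-logit))


def _sample_record(
    rng: np.random.Generator, stratum: int, config: ConstraintConfig
) -> dict[str, float]:
    """A dosimetric record whose violation counts land in the requested
    plan-quality stratum (0: full weight, 1: half, 2: quarter)."""
    metrics = list(config.metrics)
    hard_metrics = [m for m in metrics if m in config.hard]
    status = {m: "ok" for m in metrics}
    if stratum == 0:
        n_aim = int(rng.integers(0, 3))  # <= 2 aim violations, no hard
        for m in rng.choice(metrics, size=n_aim, replace=False):
            status[m] = "aim"
    elif stratum == 1:
        n_aim = int(rng.integers(3, len(metrics) + 1))
        for m in rng.choice(metrics, size=n_aim, replace=False):
            status[m] = "aim"
    else:
        n_hard = int(rng.integers(1, 3))
        for m in rng.choice(hard_metrics, size=n_hard, replace=False):
            status[m] = "hard"
        for m in metrics:
            if status[m] == "ok" and rng.random() < 0.3:
                status[m] = "aim"

    record: dict[str, float] = {}
    for m in metrics:
        aim = config.aims[m]
        hard = config.hard.get(m)
        sgn = 1.0 if aim.op == ">=" else -1.0
        if status[m] == "ok":
            record[m] = aim.value + sgn * rng.uniform(0.5, 8.0)
        elif status[m] == "aim":
            if hard is not None:
                # between the aim and the (laxer) hard bound
                span = abs(aim.value - hard.value)
                record[m] = aim.value - sgn * rng.uniform(0.1, max(span - 0.1, 0.2))
            else:
                record[m] = aim.value - sgn * rng.uniform(0.5, 8.0)
        else:
            record[m] = hard.value - sgn * rng.uniform(0.5, 6.0)
    return record


def generate_cohort(
    config: CohortConfig | None = None,
    constraint_config: ConstraintConfig | None = None,
) -> list[SyntheticFraction]:
    """Generate a cohort of synthetic treatment fractions.

    Geometry is sampled per fraction, the applicator label drawn from the
    logistic model, and the fraction accepted only while its class bucket
    (n_ic / n_is) still has room — rejection sampling that hits the
    configured class counts exactly while preserving the label-geometry
    association. Plan-quality strata are drawn to the configured
    proportions, then low-quality strata are swapped toward fractions whose
    label disagrees with the deterministic geometry rule (lateral extent
    > 25 mm or volume > 30 cm^3 implies IS), emulating sub-optimal
    applicator choices leading to sub-optimal plans.
    """
    cfg = config if config is not None else CohortConfig()
    cc = constraint_config if constraint_config is not None else ConstraintConfig.default()
    rng = np.random.default_rng(cfg.seed)

    need = {"IC": cfg.n_ic, "IS": cfg.n_is}
    accepted: list[SyntheticFraction] = []
    attempts, cap = 0, cfg.rejection_cap * cfg.n_fractions
    while len(accepted) < cfg.n_fractions:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                "label rejection sampling exceeded its cap; the configured "
                "class counts are infeasible under the label-model "
                "coefficients — adjust beta0/beta_lat/beta_vol"
            )
        geom = _sample_geometry(rng, cfg)
        struct, frame, true_vol, true_lat = _build_fraction_geometry(geom, cfg)
        p_is = _label_probability(true_lat, true_vol, cfg)
        label = "IS" if rng.random() < p_is else "IC"
        if need[label] == 0:
            continue
        need[label] -= 1
        accepted.append(
            SyntheticFraction(
                fraction_id=len(accepted),
                structure_set=struct,
                frame=frame,
                record={},
                label=label,
                true_volume=true_vol,
                true_lat_max=true_lat,
                stratum_weight=1.0,
            )
        )

    # plan-quality strata: multinomial draw, then enrichment swaps toward
    # label-vs-geometry mismatches (marginal counts preserved exactly)
    strata = rng.choice(3, size=cfg.n_fractions, p=cfg.stratum_probs)
    rule_label = np.array(
        [
            "IS" if (f.true_lat_max > 25.0 or f.true_volume > 30.0) else "IC"
            for f in accepted
        ]
    )
    labels = np.array([f.label for f in accepted])
    mismatched = np.flatnonzero(labels != rule_label)
    matched = np.flatnonzero(labels == rule_label)
    if len(mismatched) and len(matched):
        for i in matched:
            if strata[i] > 0 and rng.random() < cfg.mismatch_enrichment:
                pool = mismatched[strata[mismatched] == 0]
                if len(pool):
                    j = int(rng.choice(pool))
                    strata[i], strata[j] = strata[j], strata[i]

    weights = (1.0, 0.5, 0.25)
    for f, s in zip(accepted, strata):
        f.record = _sample_record(rng, int(s), cc)
        f.stratum_weight = weights[int(s)]
        ac = ApplicatorClass(f.label)
        f.frame = ApplicatorFrame(**_CANONICAL_FRAME, applicator_class=ac)
    return accepted


def label_model_oracle_accuracy(
    fractions: Sequence[SyntheticFraction],
    config: CohortConfig | None = None,
    threshold: str = "optimal",
    n_mc: int = 100_000,
    seed: int = 12345,
) -> float:
    """Accuracy of the generative label model's own decision rule on a cohort.

    With ``threshold="optimal"`` this is the Bayes rule of the
    class-rebalanced cohort (the posterior adjusted for the rejection
    sampling, estimated by Monte-Carlo integration of the sampling-marginal
    class probability); with ``threshold="balanced"`` it thresholds the raw
    label-model probability at 0.5 — the effective rule a classifier trained
    on class-balanced (oversampled) data implements. The two bracket what
    any classifier can achieve on the synthetic labels: the gap between them
    is the cost of the balanced training threshold, and the optimal value is
    the irreducible label-noise ceiling.
    """
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(seed)
    # sampling-marginal P(IS) before rebalancing
    med = np.asarray(cfg.hrctv_semi_axis_medians)
    semi = med * np.exp(rng.normal(0.0, cfg.hrctv_sigma_log, (n_mc, 3)))
    offm = np.abs(rng.normal(0.0, cfg.lateral_offset_sigma, n_mc))
    ang = rng.uniform(0.0, 2.0 * np.pi, n_mc)
    off = np.column_stack([offm * np.cos(ang), offm * np.sin(ang)])
    vol = 4.0 / 3.0 * np.pi * semi.prod(axis=1) / 1000.0
    th = np.linspace(0.0, 2.0 * np.pi, 360, endpoint=False)
    lat = np.hypot(
        off[:, 0, None] + semi[:, 0, None] * np.cos(th),
        off[:, 1, None] + semi[:, 1, None] * np.sin(th),
    ).max(axis=1)
    logit = (
        cfg.beta0 + cfg.beta_lat * (lat - 25.0) + cfg.beta_vol * (vol - 30.0)
    )
    p_is_marginal = float((1.0 / (1.0 + np.exp(-logit))).mean())

    p = np.array(
        [_label_probability(f.true_lat_max, f.true_volume, cfg) for f in fractions]
    )
    y = np.array([f.label for f in fractions])
    if threshold == "balanced":
        pred = np.where(p >= 0.5, "IS", "IC")
    elif threshold == "optimal":
        pi_is = cfg.n_is / cfg.n_fractions
        num_is = pi_is * p / p_is_marginal
        num_ic = (1.0 - pi_is) * (1.0 - p) / (1.0 - p_is_marginal)
        pred = np.where(num_is >= num_ic, "IS", "IC")
    else:
        raise ValueError(f"unknown threshold {threshold!r}")
    return float((pred == y).mean())


# ---------------------------------------------------------------------------
# on-disk cohort layout (internal_json structure sets + CSV manifest)


def write_cohort(fractions: Sequence[SyntheticFraction], out_dir: str | Path) -> Path:
    """Write structure sets as internal_json plus a manifest CSV holding
    labels, dosimetric metrics, and generative covariates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in fractions:
        fname = f"fraction_{f.fraction_id:04d}.json"
        write_structure_set(f.structure_set, out / fname)
        rows.append(
            {
                "fraction_id": f.fraction_id,
                "structure_file": fname,
                "label": f.label,
                "true_volume_cm3": f.true_volume,
                "true_lat_max_mm": f.true_lat_max,
                **{m: f.record.get(m, np.nan) for m in EMBRACE_METRICS},
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort_manifest(manifest: str | Path) -> pd.DataFrame:
    return pd.read_csv(manifest)
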