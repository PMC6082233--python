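"""Synthetic metaphase plates: calibrated variety templates plus noise.

A :class:`VarietyTemplate` is an idealized haploid complement (eight pair
specs with short/long arm and satellite lengths) whose *noiseless* diploid
plate reproduces a requested triple of karyotype statistics — CV_CL (%),
M_CA (%) and TCL (um) — while every pair keeps its intended morphological
class.  :func:`calibrate_template` finds such a complement
deterministically:

1.  *Centromeric asymmetry placement.*  Each pair's CA value starts at the
    midpoint of its class's CA bin (CA and arm ratio are equivalent,
    CA = 100 (r-1)/(r+1)); a single shift, applied to all pairs and clamped
    to keep a safety margin from the class boundaries, is solved by
    bisection so the complement's mean CA hits the M_CA target.  Arm ratios
    follow as r = (100+CA)/(100-CA).
2.  *Length profile.*  Pair lengths follow a decreasing exponential profile
    CL_i ∝ exp(b s_i) (s_i an equally spaced grid on [1, -1]); the spread b
    is solved by bisection so the plate's CV_CL hits its target.  The
    profile is always positive and naturally bimodal-looking, matching the
    large-versus-small chromosome groups typical of *Alstroemeria*.
3.  *Scale.*  All lengths are rescaled once so TCL hits its target
    (CV_CL and M_CA are scale-invariant).

Both bisections evaluate the statistics on the actual noiseless plate
(through the :mod:`~karyomorph.asymmetry` functions), including satellites
and any homolog heteromorphism, so zero-noise simulation followed by
analysis inverts calibration exactly.

:func:`simulate_plate` adds measurement/contraction noise: each homolog's
total arm length is scaled by multiplicative lognormal noise (CV =
``noise_cv``), its short-arm fraction is perturbed by Gaussian noise (SD =
``arm_split_sd``, clamped so S <= L), and the satellite is scaled by the
same factor as the arms.  Heteromorphism is a deterministic relative offset
on one homolog's long arm.  A single integer seed fully determines every
output; per-plate seeds derive from ``numpy.random.SeedSequence((seed,
plate_index))``.

Templates for the ten studied populations of the *A. magnifica* complex are
packaged, calibrated on demand from their published CV_CL/M_CA/TCL values
and variety formulas (the var. *tofoensis* template carries the pair-5
homolog length heteromorphism).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import CalibrationError, ValidationError
from .karyotype import expand_formula, formula_from_classes
from .measurements import ChromosomeMeasurement, MetaphasePlate
from .morphometrics import DEFAULT_THRESHOLDS, MorphClass, classify
from .asymmetry import cv_cl, m_ca, tcl

#: Default relative SD of the per-chromosome multiplicative length noise.
DEFAULT_NOISE_CV = 0.03
#: Default SD of the additive perturbation of the short-arm fraction.
DEFAULT_ARM_SPLIT_SD = 0.01
#: Satellite length as a fraction of total pair length for satellited pairs.
DEFAULT_SATELLITE_FRACTION = 0.10
#: Safety margin (CA percentage points) kept from class-bin boundaries so
#: that arm-split noise (SD ~2 CA points per chromosome) rarely flips a
#: chromosome's class.
DEFAULT_CA_MARGIN = 5.0
#: Fraction of a class's (clamped) CA bin spanned by the pairs sharing that
#: class.  Distinct pairs of one class get distinct centromere positions —
#: as in real karyotypes — which keeps homology identifiable: with
#: identical arm ratios the pairing dissimilarity's ratio term is pure
#: noise between same-class pairs.
DEFAULT_CA_SPREAD = 0.5


@dataclass(frozen=True)
class PairSpec:
    """Idealized homolog pair: arm and satellite lengths plus intended class."""

    short_arm: float
    long_arm: float
    satellite: float
    satellite_arm: str
    cls_label: str

    @property
    def total(self) -> float:
        return self.short_arm + self.long_arm + self.satellite


@dataclass(frozen=True)
class Heteromorphism:
    """Length heteromorphism: one homolog of pair ``pair_rank`` (1-based,
    longest first) carries a long arm longer by ``long_arm_offset`` (relative)."""

    pair_rank: int
    long_arm_offset: float


@dataclass(frozen=True)
class VarietyTemplate:
    """Generative spec of one population's karyotype."""

    name: str
    pair_specs: tuple[PairSpec, ...]
    noise_cv: float = DEFAULT_NOISE_CV
    arm_split_sd: float = DEFAULT_ARM_SPLIT_SD
    heteromorphism: Heteromorphism | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair_specs", tuple(self.pair_specs))
        for i, spec in enumerate(self.pair_specs):
            probe = ChromosomeMeasurement(
                self.name, "template", i + 1,
                spec.short_arm, spec.long_arm, spec.satellite, spec.satellite_arm,
            )
            got = classify(probe).label
            if got != spec.cls_label:
                raise ValidationError(
                    f"template {self.name}: pair {i + 1} classifies as {got}, "
                    f"intended {spec.cls_label}"
                )
        if self.heteromorphism is not None:
            h = self.heteromorphism
            if not 1 <= h.pair_rank <= len(self.pair_specs):
                raise ValidationError(f"heteromorphism pair_rank {h.pair_rank} out of range")
            if h.long_arm_offset <= -1:
                raise ValidationError("heteromorphism offset must be > -1")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_specs)

    @property
    def formula(self) -> str:
        return formula_from_classes([s.cls_label for s in self.pair_specs])


def template_to_dict(template: VarietyTemplate) -> dict:
    """Human-readable (JSON-serializable) form of a template."""
    d = {
        "name": template.name,
        "noise_cv": template.noise_cv,
        "arm_split_sd": template.arm_split_sd,
        "pairs": [dataclasses.asdict(s) for s in template.pair_specs],
    }
    if template.heteromorphism:
        d["heteromorphism"] = dataclasses.asdict(template.heteromorphism)
    return d


def template_from_dict(d: Mapping) -> VarietyTemplate:
    het = d.get("heteromorphism")
    return VarietyTemplate(
        name=d["name"],
        pair_specs=tuple(PairSpec(**p) for p in d["pairs"]),
        noise_cv=d.get("noise_cv", DEFAULT_NOISE_CV),
        arm_split_sd=d.get("arm_split_sd", DEFAULT_ARM_SPLIT_SD),
        heteromorphism=Heteromorphism(**het) if het else None,
    )


# ---------------------------------------------------------------------------
# noiseless plate and calibration
# ---------------------------------------------------------------------------

def _build_plate(
    specs: Sequence[PairSpec],
    het: Heteromorphism | None,
    population_id: str,
    plate_id: str,
) -> MetaphasePlate:
    chroms = []
    cid = 1
    for rank, spec in enumerate(specs, start=1):
        for member in range(2):
            long_arm = spec.long_arm
            if het is not None and rank == het.pair_rank and member == 1:
                long_arm *= 1.0 + het.long_arm_offset
            chroms.append(
                ChromosomeMeasurement(
                    population_id, plate_id, cid,
                    spec.short_arm, long_arm, spec.satellite, spec.satellite_arm,
                )
            )
            cid += 1
    return MetaphasePlate(population_id, plate_id, tuple(chroms))


def noiseless_plate(template: VarietyTemplate, plate_id: str = "noiseless") -> MetaphasePlate:
    """The template's idealized diploid plate (heteromorphism applied, no noise)."""
    return _build_plate(template.pair_specs, template.heteromorphism,
                        template.name, plate_id)


def _bisect(f: Callable[[float], float], lo: float, hi: float, iters: int = 100) -> float:
    """Root of a monotone nondecreasing f on [lo, hi] (clamped to the bracket)."""
    flo, fhi = f(lo), f(hi)
    if flo > 0:
        return lo
    if fhi < 0:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ca_bounds(margin: float) -> dict[str, tuple[float, float]]:
    """Clamped CA interval per base class, derived from the arm-ratio bins."""
    bounds = {}
    thr = list(DEFAULT_THRESHOLDS) + [("_", np.inf)]
    for (label, lo_r), (_, hi_r) in zip(thr, thr[1:]):
        lo_ca = 100.0 * (lo_r - 1.0) / (lo_r + 1.0)
        hi_ca = 100.0 if np.isinf(hi_r) else 100.0 * (hi_r - 1.0) / (hi_r + 1.0)
        # m's lower edge (r = 1, CA = 0) cannot be crossed downward, so no
        # margin is needed there; every interior boundary gets the margin.
        lo_clamped = lo_ca if lo_ca == 0.0 else lo_ca + margin
        hi_clamped = hi_ca - margin
        bounds[label] = (lo_clamped, hi_clamped)
    return bounds


def _normalize_targets(targets: Mapping[str, float]) -> dict[str, float]:
    """Accept both TCL and TLC spellings; return {cv_cl, m_ca, tcl}."""
    t = {k.lower(): float(v) for k, v in targets.items()}
    if "tlc" in t and "tcl" not in t:
        t["tcl"] = t.pop("tlc")
    missing = {"cv_cl", "m_ca", "tcl"} - set(t)
    if missing:
        raise ValidationError(f"missing calibration target(s): {sorted(missing)}")
    return {k: t[k] for k in ("cv_cl", "m_ca", "tcl")}


def calibrate_template(
    formula: str,
    targets: Mapping[str, float],
    name: str = "template",
    heteromorphism: Heteromorphism | None = None,
    noise_cv: float = DEFAULT_NOISE_CV,
    arm_split_sd: float = DEFAULT_ARM_SPLIT_SD,
    satellite_fraction: float = DEFAULT_SATELLITE_FRACTION,
    ca_margin: float = DEFAULT_CA_MARGIN,
    ca_spread: float = DEFAULT_CA_SPREAD,
    tol: float = 0.01,
) -> VarietyTemplate:
    """Deterministically calibrate a template to (CV_CL, M_CA, TCL) targets.

    Raises :class:`CalibrationError` (reporting the residuals achieved) when
    the targets are infeasible for the formula's class constraints, e.g. an
    M_CA outside the range reachable while every pair stays in its class bin.
    """
    tgt = _normalize_targets(targets)
    if tgt["tcl"] <= 0 or tgt["cv_cl"] < 0 or not 0 <= tgt["m_ca"] < 100:
        raise ValidationError(f"targets out of range: {tgt}")
    classes = expand_formula(formula)
    n = len(classes)
    bounds = _ca_bounds(ca_margin)
    los = np.array([bounds[c.base][0] for c in classes])
    his = np.array([bounds[c.base][1] for c in classes])
    # Base CA positions: pairs sharing a class are spread evenly around the
    # centre of their (clamped) bin so every pair has a distinct morphology.
    mids = np.empty(n)
    for base in {c.base for c in classes}:
        idx = [i for i, c in enumerate(classes) if c.base == base]
        lo, hi = bounds[base]
        centre, span = 0.5 * (lo + hi), ca_spread * (hi - lo)
        offsets = (np.linspace(-0.5, 0.5, len(idx)) if len(idx) > 1
                   else np.zeros(1)) * span
        mids[idx] = centre + offsets

    def member_cas(ca: np.ndarray) -> np.ndarray:
        """CA of all 2n members, heteromorphism included."""
        cas = np.repeat(ca, 2)
        if heteromorphism is not None:
            i = 2 * (heteromorphism.pair_rank - 1) + 1
            r = (100.0 + cas[i]) / (100.0 - cas[i]) * (1.0 + heteromorphism.long_arm_offset)
            cas[i] = 100.0 * (r - 1.0) / (r + 1.0)
        return cas

    delta = _bisect(lambda d: member_cas(np.clip(mids + d, los, his)).mean() - tgt["m_ca"],
                    -120.0, 120.0)
    ca = np.clip(mids + delta, los, his)
    ratios = (100.0 + ca) / (100.0 - ca)

    def specs_for(weights: np.ndarray) -> list[PairSpec]:
        out = []
        for w, r, c in zip(weights, ratios, classes):
            sat = satellite_fraction * w if c.satellited else 0.0
            arms = w - sat
            short = arms / (1.0 + r)
            out.append(PairSpec(short, arms - short,
                                sat, "short" if c.satellited else "none", c.label))
        return out

    grid = np.linspace(1.0, -1.0, n)

    def cv_at(b: float) -> float:
        plate = _build_plate(specs_for(np.exp(b * grid)), heteromorphism, name, "cal")
        return cv_cl(plate)

    b = _bisect(lambda x: cv_at(x) - tgt["cv_cl"], 0.0, 8.0)
    weights = np.exp(b * grid)
    plate = _build_plate(specs_for(weights), heteromorphism, name, "cal")
    weights *= tgt["tcl"] / tcl(plate)

    template = VarietyTemplate(
        name=name,
        pair_specs=tuple(specs_for(weights)),
        noise_cv=noise_cv,
        arm_split_sd=arm_split_sd,
        heteromorphism=heteromorphism,
    )
    check = noiseless_plate(template)
    achieved = {"cv_cl": cv_cl(check), "m_ca": m_ca(check), "tcl": tcl(check)}
    residuals = {k: achieved[k] - tgt[k] for k in achieved}
    for k, res in residuals.items():
        if abs(res) > tol * max(tgt[k], 1.0):
            raise CalibrationError(
                f"cannot reach {k} = {tgt[k]} for formula '{formula}' "
                f"(achieved {achieved[k]:.3f})",
                residuals=residuals,
            )
    return template


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_plate(
    template: VarietyTemplate,
    seed: int,
    population_id: str | None = None,
    plate_id: str | None = None,
) -> MetaphasePlate:
    """Simulate one noisy metaphase plate; the same seed gives the same plate."""
    rng = np.random.default_rng(seed)
    pop = population_id if population_id is not None else template.name
    pid = plate_id if plate_id is not None else f"sim-{seed}"
    sigma = float(np.sqrt(np.log1p(template.noise_cv ** 2)))
    het = template.heteromorphism
    chroms = []
    cid = 1
    for rank, spec in enumerate(template.pair_specs, start=1):
        for member in range(2):
            scale = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma)
            frac0 = spec.short_arm / (spec.short_arm + spec.long_arm)
            frac = float(np.clip(frac0 + rng.normal(0.0, template.arm_split_sd),
                                 0.005, 0.5))
            arms = (spec.short_arm + spec.long_arm) * scale
            short, long_ = frac * arms, (1.0 - frac) * arms
            if het is not None and rank == het.pair_rank and member == 1:
                long_ *= 1.0 + het.long_arm_offset
            chroms.append(
                ChromosomeMeasurement(
                    pop, pid, cid, short, long_,
                    spec.satellite * scale, spec.satellite_arm,
                )
            )
            cid += 1
    return MetaphasePlate(pop, pid, tuple(chroms))


def plate_seed(seed: int, index: int) -> int:
    """Derived seed for plate ``index``: SeedSequence((seed, index))."""
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0])


def simulate_population(
    template: VarietyTemplate,
    n_plates: int,
    seed: int,
    population_id: str | None = None,
) -> list[MetaphasePlate]:
    """Simulate a population of plates with per-plate derived seeds."""
    if n_plates < 1:
        raise ValidationError("n_plates must be >= 1")
    pop = population_id if population_id is not None else template.name
    return [
        simulate_plate(template, plate_seed(seed, i), pop, f"p{i + 1:02d}")
        for i in range(n_plates)
    ]


# ---------------------------------------------------------------------------
# packaged population templates (A. magnifica complex)
# ---------------------------------------------------------------------------

#: Published haploid formulas per variety (magnifica and sierrae share one).
VARIETY_FORMULAS: dict[str, str] = {
    "magnifica": "2m + 1sm + 2st + 2st-sat + 1t-sat",
    "sierrae": "2m + 1sm + 2st + 2st-sat + 1t-sat",
    "magenta": "2m + 2sm + 1st + 2st-sat + 1t-sat",
    "tofoensis": "2m + 1sm + 1st + 2t + 2t-sat",
}

#: Published per-population targets: variety, CV_CL (%), M_CA (%), TCL (um),
#: and the printed SDs (used by recovery tests as tolerances).
POPULATION_TABLE: dict[str, dict] = {
    "4408": {"variety": "magnifica", "cv_cl": 62.0, "cv_cl_sd": 2.4,
             "m_ca": 45.0, "m_ca_sd": 1.6, "tcl": 128.2, "tcl_sd": 6.2},
    "4411": {"variety": "magnifica", "cv_cl": 60.0, "cv_cl_sd": 4.3,
             "m_ca": 42.0, "m_ca_sd": 2.3, "tcl": 136.5, "tcl_sd": 8.3},
    "4414": {"variety": "magnifica", "cv_cl": 62.0, "cv_cl_sd": 3.5,
             "m_ca": 47.0, "m_ca_sd": 2.0, "tcl": 130.4, "tcl_sd": 5.9},
    "4406": {"variety": "sierrae", "cv_cl": 46.0, "cv_cl_sd": 3.6,
             "m_ca": 51.0, "m_ca_sd": 1.8, "tcl": 187.5, "tcl_sd": 7.2},
    "4407": {"variety": "sierrae", "cv_cl": 47.0, "cv_cl_sd": 4.2,
             "m_ca": 50.0, "m_ca_sd": 2.1, "tcl": 193.5, "tcl_sd": 6.8},
    "4409": {"variety": "tofoensis", "cv_cl": 55.0, "cv_cl_sd": 3.9,
             "m_ca": 55.0, "m_ca_sd": 1.5, "tcl": 173.9, "tcl_sd": 9.2},
    "4379": {"variety": "magenta", "cv_cl": 54.0, "cv_cl_sd": 4.8,
             "m_ca": 51.0, "m_ca_sd": 2.4, "tcl": 104.6, "tcl_sd": 8.8},
    "4380": {"variety": "magenta", "cv_cl": 55.0, "cv_cl_sd": 5.3,
             "m_ca": 51.0, "m_ca_sd": 1.3, "tcl": 100.1, "tcl_sd": 4.6},
    "4381": {"variety": "magenta", "cv_cl": 55.0, "cv_cl_sd": 4.4,
             "m_ca": 49.0, "m_ca_sd": 1.8, "tcl": 109.4, "tcl_sd": 5.2},
    "4383": {"variety": "magenta", "cv_cl": 53.0, "cv_cl_sd": 3.1,
             "m_ca": 50.0, "m_ca_sd": 2.2, "tcl": 110.4, "tcl_sd": 5.9},
}

#: var. tofoensis carries a length heteromorphism between the homologs of
#: pair 5: one homolog's long arm is 20% longer.
TOFOENSIS_HETEROMORPHISM = Heteromorphism(pair_rank=5, long_arm_offset=0.2)


def available_populations() -> list[str]:
    """IDs of the packaged population templates."""
    return sorted(POPULATION_TABLE)


@lru_cache(maxsize=None)
def packaged_template(population_id: str) -> VarietyTemplate:
    """Calibrated template for one packaged population (e.g. ``"4408"``)."""
    try:
        row = POPULATION_TABLE[population_id]
    except KeyError:
        raise KeyError(
            f"unknown population {population_id!r}; available: "
            f"{', '.join(available_populations())}"
        ) from None
    het = TOFOENSIS_HETEROMORPHISM if row["variety"] == "tofoensis" else None
    return calibrate_template(
        VARIETY_FORMULAS[row["variety"]],
        {"cv_cl": row["cv_cl"], "m_ca": row["m_ca"], "tcl": row["tcl"]},
        name=population_id,
        heteromorphism=het,
    )
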