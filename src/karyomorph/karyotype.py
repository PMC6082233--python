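"""Homolog pairing, consensus karyotypes, formula strings and idiograms.

Within a metaphase plate, homologous chromosomes are identified by solving
a minimum-weight perfect matching over all chromosome pairs, with the
dissimilarity

    d(a, b) = |CL_a - CL_b| / mean(CL_a, CL_b) + w * |r_a - r_b|,  w = 0.5,

i.e. relative length difference plus a weighted arm-ratio difference.  The
matching is solved exactly (blossom algorithm via networkx), so plates of
the usual 2n = 16 pose no difficulty.

Pairs from several plates of one population are then rank-aligned by
decreasing mean length and averaged into a consensus haploid karyotype,
from which the karyotype formula (e.g. ``2m + 1sm + 2st + 2st-sat +
1t-sat``) and an idiogram are derived.
"""

from __future__ import annotations

import itertools
import json
import re
from collections import Counter
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Sequence

import networkx as nx

from .errors import PairingError, ValidationError
from .measurements import ChromosomeMeasurement, MetaphasePlate
from .morphometrics import (
    CLASS_ORDER,
    DEFAULT_THRESHOLDS,
    MorphClass,
    arm_ratio,
    chromosome_length,
    classify,
)

#: Weight of the arm-ratio term in the pairing dissimilarity.
PAIRING_WEIGHT = 0.5
#: Relative chromosome-length difference above which a pair of homologs is
#: called heteromorphic (in addition to any class disagreement).
HETEROMORPHISM_THRESHOLD = 0.15


# ---------------------------------------------------------------------------
# homolog pairing
# ---------------------------------------------------------------------------

def pairing_dissimilarity(
    a: ChromosomeMeasurement, b: ChromosomeMeasurement, weight: float = PAIRING_WEIGHT
) -> float:
    """Dissimilarity between two chromosomes for homolog matching."""
    cla, clb = chromosome_length(a), chromosome_length(b)
    return abs(cla - clb) / fmean((cla, clb)) + weight * abs(
        arm_ratio(a) - arm_ratio(b)
    )


@dataclass(frozen=True)
class HomologPair:
    """Two chromosomes of one plate identified as homologs.

    Mean fields are arithmetic means of the members; ``cls`` is the class of
    the pseudo-chromosome built from the mean arms.  ``heteromorphic`` marks
    pairs whose members disagree in class or differ in total length by more
    than the heteromorphism threshold.
    """

    members: tuple[ChromosomeMeasurement, ChromosomeMeasurement]
    mean_short: float
    mean_long: float
    mean_satellite: float
    satellite_arm: str
    cls: MorphClass
    heteromorphic: bool

    @property
    def mean_length(self) -> float:
        return self.mean_short + self.mean_long + self.mean_satellite


def _make_pair(
    a: ChromosomeMeasurement,
    b: ChromosomeMeasurement,
    thresholds: tuple[tuple[str, float], ...],
    het_threshold: float,
) -> HomologPair:
    mean_short = (a.short_arm + b.short_arm) / 2.0
    mean_long = (a.long_arm + b.long_arm) / 2.0
    mean_sat = (a.satellite + b.satellite) / 2.0
    sat_arm = a.satellite_arm if a.satellite_arm != "none" else b.satellite_arm
    pseudo = ChromosomeMeasurement(
        a.population_id, a.plate_id, -1, mean_short, mean_long, mean_sat, sat_arm
    )
    cla, clb = chromosome_length(a), chromosome_length(b)
    rel_diff = abs(cla - clb) / fmean((cla, clb))
    het = (
        classify(a, thresholds).label != classify(b, thresholds).label
        or rel_diff > het_threshold
    )
    return HomologPair(
        members=(a, b),
        mean_short=mean_short,
        mean_long=mean_long,
        mean_satellite=mean_sat,
        satellite_arm=sat_arm,
        cls=classify(pseudo, thresholds),
        heteromorphic=het,
    )


def pair_homologs(
    plate: MetaphasePlate,
    weight: float = PAIRING_WEIGHT,
    het_threshold: float = HETEROMORPHISM_THRESHOLD,
    thresholds: tuple[tuple[str, float], ...] = DEFAULT_THRESHOLDS,
) -> list[HomologPair]:
    """Pair a plate's chromosomes into homologs by exact min-weight matching.

    Returns pairs sorted by decreasing mean total length.  Raises
    :class:`PairingError` on an odd chromosome count.
    """
    chroms = plate.chromosomes
    if len(chroms) % 2:
        raise PairingError(
            f"plate {plate.population_id}/{plate.plate_id} has an odd "
            f"chromosome count ({len(chroms)})"
        )
    g = nx.Graph()
    g.add_nodes_from(range(len(chroms)))
    for i, j in itertools.combinations(range(len(chroms)), 2):
        g.add_edge(i, j, weight=pairing_dissimilarity(chroms[i], chroms[j], weight))
    matching = nx.min_weight_matching(g)
    pairs = [
        _make_pair(chroms[min(i, j)], chroms[max(i, j)], thresholds, het_threshold)
        for i, j in matching
    ]
    pairs.sort(key=lambda p: (-p.mean_length, p.members[0].chrom_id))
    return pairs


def matching_cost(pairs: Iterable[HomologPair], weight: float = PAIRING_WEIGHT) -> float:
    """Total dissimilarity of a set of homolog pairs."""
    return sum(pairing_dissimilarity(*p.members, weight) for p in pairs)


# ---------------------------------------------------------------------------
# consensus karyotype
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusPair:
    """One homolog pair of the consensus haploid karyotype (rank-averaged)."""

    rank: int
    mean_short: float
    mean_long: float
    mean_satellite: float
    satellite_arm: str
    cls: MorphClass
    heteromorphic: bool = False

    @property
    def mean_length(self) -> float:
        return self.mean_short + self.mean_long + self.mean_satellite


@dataclass(frozen=True)
class KaryotypeModel:
    """Consensus haploid complement: ordered pairs (longest first) + formula."""

    pairs: tuple[ConsensusPair, ...]
    n_haploid: int
    formula: str

    @property
    def diploid_number(self) -> int:
        return 2 * self.n_haploid


def _majority(values: Sequence[str]) -> tuple[str, bool]:
    """Most common value and whether the vote was a strict majority win."""
    counts = Counter(values).most_common()
    top, top_n = counts[0]
    tie = len(counts) > 1 and counts[1][1] == top_n
    return top, not tie


def consensus_karyotype(
    plates: Sequence[MetaphasePlate],
    weight: float = PAIRING_WEIGHT,
    het_threshold: float = HETEROMORPHISM_THRESHOLD,
    thresholds: tuple[tuple[str, float], ...] = DEFAULT_THRESHOLDS,
) -> KaryotypeModel:
    """Aggregate plates of one population into a consensus haploid karyotype.

    Per plate, homolog pairs are sorted by decreasing mean length and
    rank-aligned across plates; consensus arm lengths are across-plate means
    at each rank, the consensus base class is the majority vote of per-plate
    classes (ties broken by reclassifying the mean arms), and the satellite
    flag/arm follow the majority of plates.
    """
    if not plates:
        raise ValidationError("consensus_karyotype needs at least one plate")
    counts = {len(p) for p in plates}
    if len(counts) != 1:
        raise ValidationError(f"plates have differing chromosome counts: {sorted(counts)}")

    per_plate = [pair_homologs(p, weight, het_threshold, thresholds) for p in plates]
    n_pairs = len(per_plate[0])
    consensus: list[ConsensusPair] = []
    for rank in range(n_pairs):
        at_rank = [pairs[rank] for pairs in per_plate]
        mean_short = fmean(p.mean_short for p in at_rank)
        mean_long = fmean(p.mean_long for p in at_rank)
        satellited = sum(p.satellite_arm != "none" for p in at_rank) * 2 > len(at_rank)
        if satellited:
            with_sat = [p for p in at_rank if p.satellite_arm != "none"]
            mean_sat = fmean(p.mean_satellite for p in with_sat)
            sat_arm, _ = _majority([p.satellite_arm for p in with_sat])
        else:
            mean_sat, sat_arm = 0.0, "none"
        base, decisive = _majority([p.cls.base for p in at_rank])
        if not decisive:
            pseudo = ChromosomeMeasurement(
                at_rank[0].members[0].population_id, "consensus", rank + 1,
                mean_short, mean_long, mean_sat, sat_arm,
            )
            base = classify(pseudo, thresholds).base
        het = sum(p.heteromorphic for p in at_rank) * 2 > len(at_rank)
        consensus.append(
            ConsensusPair(
                rank=rank + 1,
                mean_short=mean_short,
                mean_long=mean_long,
                mean_satellite=mean_sat,
                satellite_arm=sat_arm,
                cls=MorphClass(base, satellited),
                heteromorphic=het,
            )
        )
    consensus.sort(key=lambda p: -p.mean_length)
    consensus = [
        ConsensusPair(i + 1, p.mean_short, p.mean_long, p.mean_satellite,
                      p.satellite_arm, p.cls, p.heteromorphic)
        for i, p in enumerate(consensus)
    ]
    model = KaryotypeModel(
        pairs=tuple(consensus),
        n_haploid=n_pairs,
        formula=formula_from_classes([p.cls for p in consensus]),
    )
    return model


# ---------------------------------------------------------------------------
# karyotype formula
# ---------------------------------------------------------------------------

def formula_from_classes(classes: Iterable[MorphClass | str]) -> str:
    """Canonical formula string from pair classes, e.g. ``"2m + 1sm"``.

    Classes are counted and emitted in the order m, m-sat, sm, sm-sat, st,
    st-sat, t, t-sat, omitting zero counts.
    """
    labels = [c.label if isinstance(c, MorphClass) else str(c) for c in classes]
    counts = Counter(labels)
    unknown = set(counts) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")
    return " + ".join(f"{counts[lab]}{lab}" for lab in CLASS_ORDER if counts[lab])


def karyotype_formula(model: KaryotypeModel) -> str:
    """Canonical haploid karyotype formula of a consensus model."""
    return formula_from_classes([p.cls for p in model.pairs])


_TERM_RE = re.compile(r"^\s*(\d+)\s*((?:m|sm|st|t)(?:-sat)?)\s*$")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a karyotype formula back into ``{label: count}``.

    Inverse of :func:`formula_from_classes` on canonical strings; tolerant
    of extra whitespace around the ``+`` separators.
    """
    counts: dict[str, int] = {}
    for term in formula.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"cannot parse formula term {term!r}")
        n, label = int(m.group(1)), m.group(2)
        if label in counts:
            raise ValueError(f"duplicate class {label!r} in formula")
        counts[label] = n
    return counts


def expand_formula(formula: str) -> list[MorphClass]:
    """Expand a formula into the list of pair classes in canonical order."""
    counts = parse_formula(formula)
    out: list[MorphClass] = []
    for label in CLASS_ORDER:
        base = label.removesuffix("-sat")
        out.extend([MorphClass(base, label.endswith("-sat"))] * counts.get(label, 0))
    return out


# ---------------------------------------------------------------------------
# idiogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdiogramGlyph:
    """Drawing geometry for one haploid pair, lengths in micrometres.

    Figures are drawn vertically, short arm up.  ``centromere_um`` is the
    distance from the top of the figure (including any satellite block and
    its constriction gap) down to the centromere.
    """

    rank: int
    label: str
    short_um: float
    long_um: float
    satellite_um: float
    satellite_arm: str
    centromere_um: float
    total_um: float


@dataclass(frozen=True)
class Idiogram:
    """Idiogram of a consensus karyotype: one glyph per pair, longest first."""

    glyphs: tuple[IdiogramGlyph, ...]
    gap_um: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "gap_um": self.gap_um,
                "glyphs": [vars(g) for g in self.glyphs],
            },
            indent=2,
            sort_keys=True,
        )

    def to_svg(self, px_per_um: float = 18.0) -> str:
        return _idiogram_svg(self, px_per_um)


#: Drawn secondary-constriction gap between a satellite and its arm (um).
SATELLITE_GAP_UM = 0.3


def build_idiogram(model: KaryotypeModel, gap_um: float = SATELLITE_GAP_UM) -> Idiogram:
    """Deterministic idiogram geometry for a consensus karyotype.

    Arm and satellite extents are the model's mean lengths; the constriction
    gap is a fixed drawing constant, so all chromatin extents scale linearly
    with the input lengths.
    """
    glyphs = []
    for p in model.pairs:
        gap = gap_um if p.satellite_arm != "none" else 0.0
        above = p.mean_short + (p.mean_satellite + gap if p.satellite_arm == "short" else 0.0)
        total = p.mean_short + p.mean_long + p.mean_satellite + gap
        glyphs.append(
            IdiogramGlyph(
                rank=p.rank,
                label=p.cls.label,
                short_um=p.mean_short,
                long_um=p.mean_long,
                satellite_um=p.mean_satellite,
                satellite_arm=p.satellite_arm,
                centromere_um=above,
                total_um=total,
            )
        )
    return Idiogram(glyphs=tuple(glyphs), gap_um=gap_um)


def _rect(x: float, y: float, w: float, h: float, fill: str) -> str:
    return (
        f'<rect x="{x:.2f}" y="{y:.2f}" width="{w:.2f}" height="{h:.2f}" '
        f'rx="{min(w, h) * 0.25:.2f}" fill="{fill}" stroke="black" stroke-width="1"/>'
    )


def _idiogram_svg(idg: Idiogram, px_per_um: float) -> str:
    """Minimal hand-rolled SVG: one column per pair, short arms up."""
    col_w, chrom_w, margin = 60.0, 22.0, 30.0
    max_total = max((g.total_um for g in idg.glyphs), default=1.0)
    height = margin * 2 + max_total * px_per_um + 20
    width = margin * 2 + col_w * len(idg.glyphs)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
        '<style>text{font-family:sans-serif;font-size:11px;}</style>',
    ]
    for i, g in enumerate(idg.glyphs):
        x = margin + i * col_w + (col_w - chrom_w) / 2
        # align all centromeres on one horizontal line
        cen_y = margin + max((gg.centromere_um for gg in idg.glyphs)) * px_per_um
        y = cen_y - g.centromere_um * px_per_um
        if g.satellite_arm == "short":
            parts.append(_rect(x, y, chrom_w, g.satellite_um * px_per_um, "#bbb"))
            y += (g.satellite_um + idg.gap_um) * px_per_um
        parts.append(_rect(x, y, chrom_w, g.short_um * px_per_um, "#777"))
        y += g.short_um * px_per_um + 2  # 2 px centromere constriction
        parts.append(_rect(x, y, chrom_w, g.long_um * px_per_um, "#777"))
        y += g.long_um * px_per_um
        if g.satellite_arm == "long":
            y += idg.gap_um * px_per_um
            parts.append(_rect(x, y, chrom_w, g.satellite_um * px_per_um, "#bbb"))
            y += g.satellite_um * px_per_um
        parts.append(
            f'<text x="{x + chrom_w / 2:.1f}" y="{y + 14:.1f}" '
            f'text-anchor="middle">{g.rank} {g.label}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)
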