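"""Homolog pairing, consensus karyotypes, formulas and idiograms."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from karyomorph import (
    MetaphasePlate,
    PairingError,
    build_idiogram,
    consensus_karyotype,
    expand_formula,
    formula_from_classes,
    karyotype_formula,
    matching_cost,
    noiseless_plate,
    packaged_template,
    pair_homologs,
    parse_formula,
    simulate_population,
)
from karyomorph.morphometrics import CLASS_ORDER

from conftest import brute_force_matching_cost, make_chrom, make_plate, random_plate


class TestPairing:
    def test_duplicated_pairs_recovered(self, duplicated_plate):
        pairs = pair_homologs(duplicated_plate)
        assert len(pairs) == 8
        assert matching_cost(pairs) == pytest.approx(0.0, abs=1e-12)
        for p in pairs:
            a, b = p.members
            assert a.short_arm == b.short_arm and a.long_arm == b.long_arm

    def test_matches_brute_force_on_random_plates(self, rng):
        for _ in range(40):
            plate = random_plate(rng, n=8)
            cost = matching_cost(pair_homologs(plate))
            assert cost == pytest.approx(brute_force_matching_cost(plate), abs=1e-9)

    def test_odd_count_hard_error(self):
        with pytest.warns(UserWarning):
            plate = MetaphasePlate("P", "p1", tuple(
                make_chrom(1, 2, cid=i) for i in range(3)))
        with pytest.raises(PairingError):
            pair_homologs(plate)

    def test_noiseless_tofoensis_flags_exactly_pair_5(self):
        """The packaged pair-5 long-arm heteromorphism is the only flagged pair."""
        plate = noiseless_plate(packaged_template("4409"))
        pairs = pair_homologs(plate)
        flagged = [i + 1 for i, p in enumerate(pairs) if p.heteromorphic]
        assert flagged == [5]

    def test_pair_means_are_member_means(self, duplicated_plate):
        for p in pair_homologs(duplicated_plate):
            a, b = p.members
            assert p.mean_short == pytest.approx((a.short_arm + b.short_arm) / 2)
            assert p.mean_long == pytest.approx((a.long_arm + b.long_arm) / 2)


class TestConsensus:
    def test_single_plate_identity(self, duplicated_plate):
        model = consensus_karyotype([duplicated_plate])
        pairs = pair_homologs(duplicated_plate)
        assert model.n_haploid == 8
        for cp, hp in zip(model.pairs, pairs):
            assert cp.mean_short == pytest.approx(hp.mean_short)
            assert cp.mean_long == pytest.approx(hp.mean_long)
            assert cp.cls.label == hp.cls.label

    def test_rank_means_match_hand_computation(self):
        """Consensus arms are across-plate means at each length rank."""
        base = [(1.0, 1.2), (0.5, 2.5)]  # one m pair, one st-ish pair
        factors = [0.9, 1.0, 1.1]
        plates = [
            make_plate([(s * f, l * f) for s, l in base for _ in range(2)],
                       plate=f"p{i}")
            for i, f in enumerate(factors)
        ]
        model = consensus_karyotype(plates)
        exp_short = [np.mean([s * f for f in factors]) for s, _ in base]
        exp_long = [np.mean([l * f for f in factors]) for _, l in base]
        # rank order: pair with the larger total first
        order = np.argsort([-(s + l) for s, l in base])
        for rank, j in enumerate(order):
            assert model.pairs[rank].mean_short == pytest.approx(exp_short[j])
            assert model.pairs[rank].mean_long == pytest.approx(exp_long[j])

    def test_permutation_invariance(self, rng):
        plates = simulate_population(packaged_template("4406"), 5, seed=9)
        model = consensus_karyotype(plates)
        shuffled = []
        for p in plates[::-1]:
            idx = rng.permutation(len(p.chromosomes))
            shuffled.append(
                MetaphasePlate(p.population_id, p.plate_id,
                               tuple(p.chromosomes[i] for i in idx))
            )
        model2 = consensus_karyotype(shuffled)
        assert model.formula == model2.formula
        for a, b in zip(model.pairs, model2.pairs):
            assert a.mean_short == pytest.approx(b.mean_short)
            assert a.mean_long == pytest.approx(b.mean_long)

    def test_differing_counts_hard_error(self):
        p1 = make_plate([(1, 2)] * 4, plate="p1")
        p2 = make_plate([(1, 2)] * 6, plate="p2")
        with pytest.raises(Exception, match="differing"):
            consensus_karyotype([p1, p2])


class TestFormula:
    def test_all_metacentric(self):
        plate = make_plate([(5.0, 5.0)] * 16)
        assert consensus_karyotype([plate]).formula == "8m"

    @pytest.mark.parametrize(
        "pop, expected",
        [
            ("4408", "2m + 1sm + 2st + 2st-sat + 1t-sat"),
            ("4409", "2m + 1sm + 1st + 2t + 2t-sat"),
            ("4383", "2m + 2sm + 1st + 2st-sat + 1t-sat"),
        ],
    )
    def test_published_formulas_from_noiseless_plates(self, pop, expected):
        model = consensus_karyotype([noiseless_plate(packaged_template(pop))])
        assert karyotype_formula(model) == expected

    def test_parse_inverse(self):
        s = "2m + 1sm + 2st + 2st-sat + 1t-sat"
        assert formula_from_classes(expand_formula(s)) == s

    @given(
        counts=st.dictionaries(
            st.sampled_from(CLASS_ORDER), st.integers(1, 5), min_size=1, max_size=8
        )
    )
    def test_emit_parse_roundtrip(self, counts):
        classes = [lab for lab in CLASS_ORDER for _ in range(counts.get(lab, 0))]
        formula = formula_from_classes(classes)
        assert parse_formula(formula) == {k: v for k, v in counts.items() if v}
        assert sum(parse_formula(formula).values()) == len(classes)

    def test_formula_counts_sum_to_n_haploid(self):
        model = consensus_karyotype([noiseless_plate(packaged_template("4406"))])
        assert sum(parse_formula(model.formula).values()) == model.n_haploid


class TestIdiogram:
    def test_single_metacentric_centromere_at_midpoint(self):
        model = consensus_karyotype([make_plate([(4.0, 4.0)] * 2)])
        idg = build_idiogram(model)
        g = idg.glyphs[0]
        assert g.centromere_um == pytest.approx(g.total_um / 2)

    def test_magnifica_geometry(self):
        model = consensus_karyotype([noiseless_plate(packaged_template("4408"))])
        idg = build_idiogram(model)
        assert len(idg.glyphs) == 8
        totals = [g.short_um + g.long_um + g.satellite_um for g in idg.glyphs]
        assert totals == sorted(totals, reverse=True)
        assert sum(g.satellite_arm != "none" for g in idg.glyphs) == 3
        svg = idg.to_svg()
        assert svg.startswith("<svg") and svg.count("<text") == 8

    def test_linearity_under_scaling(self):
        model = consensus_karyotype([noiseless_plate(packaged_template("4408"))])
        doubled = dataclasses.replace(
            model,
            pairs=tuple(
                dataclasses.replace(
                    p, mean_short=2 * p.mean_short, mean_long=2 * p.mean_long,
                    mean_satellite=2 * p.mean_satellite)
                for p in model.pairs
            ),
        )
        a, b = build_idiogram(model), build_idiogram(doubled)
        for ga, gb in zip(a.glyphs, b.glyphs):
            assert gb.short_um == pytest.approx(2 * ga.short_um)
            assert gb.long_um == pytest.approx(2 * ga.long_um)
            assert gb.satellite_um == pytest.approx(2 * ga.satellite_um)

    def test_json_export(self):
        model = consensus_karyotype([make_plate([(4.0, 4.0)] * 2)])
        import json

        data = json.loads(build_idiogram(model).to_json())
        assert len(data["glyphs"]) == 1 and data["glyphs"][0]["label"] == "m"
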