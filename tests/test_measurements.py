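"""Measurement-table I/O and domain-invariant validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from karyomorph import (
    ChromosomeMeasurement,
    MetaphasePlate,
    SchemaError,
    ValidationError,
    packaged_template,
    read_measurements,
    simulate_population,
    write_measurements,
)
from karyomorph.measurements import COLUMNS

from conftest import make_chrom, make_plate


class TestValidation:
    def test_valid_chromosome(self):
        c = make_chrom(2.0, 6.0, sat=1.0)
        assert c.satellite_arm == "short"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(short_arm=0.0, long_arm=3.0),
            dict(short_arm=-1.0, long_arm=3.0),
            dict(short_arm=4.0, long_arm=3.0),
            dict(short_arm=1.0, long_arm=3.0, satellite=-0.5),
            dict(short_arm=1.0, long_arm=3.0, satellite=0.5, satellite_arm="none"),
            dict(short_arm=1.0, long_arm=3.0, satellite=0.0, satellite_arm="short"),
            dict(short_arm=1.0, long_arm=3.0, satellite_arm="weird"),
        ],
    )
    def test_invalid_chromosome_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ChromosomeMeasurement("P", "p1", 1, **kwargs)

    @given(
        s=st.floats(0.1, 20.0),
        ratio=st.floats(1.0, 12.0),
        sat=st.one_of(st.just(0.0), st.floats(0.05, 2.0)),
        corruption=st.sampled_from(
            ["zero_short", "swap_arms", "orphan_satellite", "missing_satellite"]
        ),
    )
    def test_single_field_corruption_rejected(self, s, ratio, sat, corruption):
        """Every single-field corruption of a valid row fails validation."""
        fields = dict(
            population_id="P", plate_id="p1", chrom_id=1,
            short_arm=s, long_arm=s * ratio, satellite=sat,
            satellite_arm="short" if sat > 0 else "none",
        )
        ChromosomeMeasurement(**fields)  # sanity: valid before corruption
        if corruption == "zero_short":
            fields["short_arm"] = 0.0
        elif corruption == "swap_arms":
            fields["short_arm"], fields["long_arm"] = (
                fields["long_arm"] * 1.01, fields["short_arm"])
        elif corruption == "orphan_satellite":
            fields["satellite"], fields["satellite_arm"] = 1.0, "none"
        else:
            fields["satellite"], fields["satellite_arm"] = 0.0, "long"
        with pytest.raises(ValidationError):
            ChromosomeMeasurement(**fields)

    def test_plate_requires_consistent_ids(self):
        chroms = (make_chrom(1, 2, cid=1), make_chrom(1, 2, plate="p2", cid=2))
        with pytest.raises(ValidationError):
            MetaphasePlate("P", "p1", chroms)

    def test_odd_plate_warns(self):
        chroms = tuple(make_chrom(1, 2, cid=i) for i in range(3))
        with pytest.warns(UserWarning, match="odd"):
            MetaphasePlate("P", "p1", chroms)


class TestIO:
    def test_single_plate_file(self, tmp_path):
        plate = make_plate([(1.0, 2.0)] * 16)
        path = tmp_path / "m.csv"
        write_measurements([plate], path)
        plates = read_measurements(path)
        assert len(plates) == 1 and len(plates[0]) == 16

    def test_roundtrip_identity(self, tmp_path):
        template = packaged_template("4408")
        plates = simulate_population(template, 3, seed=11)
        path = tmp_path / "plates.csv"
        write_measurements(plates, path)
        back = read_measurements(path)
        assert len(back) == len(plates)
        orig = {(p.population_id, p.plate_id): p for p in plates}
        for p in back:
            q = orig[(p.population_id, p.plate_id)]
            for a, b in zip(
                sorted(p.chromosomes, key=lambda c: c.chrom_id),
                sorted(q.chromosomes, key=lambda c: c.chrom_id),
            ):
                assert a.short_arm == pytest.approx(b.short_arm, abs=1e-4)
                assert a.long_arm == pytest.approx(b.long_arm, abs=1e-4)
                assert a.satellite == pytest.approx(b.satellite, abs=1e-4)
                assert a.satellite_arm == b.satellite_arm

    def test_tsv_roundtrip(self, tmp_path):
        plate = make_plate([(1.0, 2.5), (1.0, 2.5)])
        path = tmp_path / "m.tsv"
        write_measurements([plate], path, delimiter="\t")
        assert len(read_measurements(path)) == 1

    def test_grouping_160_rows(self, tmp_path):
        """A 160-row file (population 4408, plates p01..p10) gives 10 plates of 16."""
        plates = simulate_population(packaged_template("4408"), 10, seed=3,
                                     population_id="4408")
        path = tmp_path / "pop.csv"
        write_measurements(plates, path)
        assert sum(1 for _ in open(path)) == 161  # header + 160 rows
        back = read_measurements(path)
        assert len(back) == 10
        assert all(len(p) == 16 for p in back)
        assert {p.population_id for p in back} == {"4408"}

    def test_output_sorted(self, tmp_path):
        plates = [
            make_plate([(1, 2), (1, 2)], pop=pop, plate=f"p{i}")
            for pop in ("B", "A")
            for i in (2, 1)
        ]
        path = tmp_path / "sorted.csv"
        write_measurements(plates, path)
        df = pd.read_csv(path)
        keys = list(zip(df.population, df.plate, df.chrom))
        assert keys == sorted(keys)

    def test_empty_collection_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_measurements([], path)
        text = path.read_text().strip().splitlines()
        assert text == [",".join(COLUMNS)]
        assert read_measurements(path) == []

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("population,plate,chrom,short_arm_um,long_arm_um\n")
        with pytest.raises(SchemaError, match="satellite_um"):
            read_measurements(path)

    def test_invalid_row_names_plate_and_chrom(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            ",".join(COLUMNS) + "\n"
            "4408,p1,1,0.0,2.0,0.0,none\n"
            "4408,p1,2,1.0,2.0,0.0,none\n"
        )
        with pytest.raises(ValidationError, match="p1.*chrom 1"):
            read_measurements(path)
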