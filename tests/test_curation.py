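"""Curation filters: structure, IQR range, positive-deviation, log transform."""

import math

import numpy as np
import pytest

from viscml.curation import (
    CuratedDataset,
    ViscosityRecord,
    curate,
    filter_positive_temperature_deviation,
    filter_range_outliers,
    filter_structures,
    log_transform_viscosity,
    read_records,
)


def rec(structure="CCO", T=300.0, mu=1.0):
    return ViscosityRecord(structure, T, mu)


class TestRecordInvariants:
    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            ViscosityRecord("CCO", 0.0, 1.0)

    def test_rejects_nonpositive_viscosity(self):
        with pytest.raises(ValueError):
            ViscosityRecord("CCO", 300.0, -1.0)


class TestReadRecords:
    def test_reads_well_formed_file(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "structure,temperature_K,viscosity_cP,source\n"
            "CCO,300,1.2,a\nCCC,310,0.8,b\nCCCC,290,2.0,c\n"
        )
        records, report = read_records(p)
        assert len(records) == 3 and not report.skipped

    def test_skips_unparseable_rows_with_line_numbers(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "structure,temperature_K,viscosity_cP\nCCO,300,abc\nCCC,310,0.8\n"
        )
        records, report = read_records(p)
        assert len(records) == 1
        assert report.skipped[0][0] == 0

    def test_celsius_converted_at_boundary(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("smiles,t_C,visc\nCCO,25,1.0\n")
        records, _ = read_records(
            p,
            {
                "structure": "smiles",
                "temperature": "t_C",
                "viscosity": "visc",
                "temperature_unit": "C",
            },
        )
        assert records[0].temperature == pytest.approx(298.15)

    def test_missing_column_is_config_error(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(KeyError):
            read_records(p)

    def test_zero_parseable_rows_is_input_error(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("structure,temperature_K,viscosity_cP\nCCO,x,y\n")
        with pytest.raises(ValueError):
            read_records(p)


class TestStructureFilter:
    @pytest.mark.parametrize(
        "smiles,kept",
        [
            ("CCO", True),  # ethanol: organic, single fragment
            ("ClC(Cl)Cl", True),  # chloroform: allowed halogens
            ("[Na+].[Cl-]", False),  # two fragments, disallowed metal
            ("O", False),  # water: no carbon
            ("CC[Sn](CC)CC", False),  # tin outside the element set
            ("not_a_smiles", False),  # parse failure
        ],
    )
    def test_element_and_fragment_rules(self, smiles, kept):
        records = [rec(smiles)]
        kept_records, removed = filter_structures(records)
        assert (len(kept_records) == 1) is kept

    def test_removal_reasons_annotated(self):
        _, removed = filter_structures([rec("xx(")])
        assert removed[0].reason == "parse_failure"


class TestRangeFilter:
    def test_derived_quantile_example(self):
        # viscosities {1,2,3,4,100}: Q1=2, Q3=4, upper fence 7 -> 100 out
        records = [rec(mu=v) for v in (1, 2, 3, 4, 100)]
        kept, removed = filter_range_outliers(records)
        assert len(kept) == 4
        assert removed[0].record.viscosity == 100

    def test_constant_values_all_kept(self):
        records = [rec(mu=2.0, T=300.0) for _ in range(5)]
        kept, removed = filter_range_outliers(records)
        assert len(kept) == 5 and not removed

    def test_single_record_kept(self):
        kept, removed = filter_range_outliers([rec()])
        assert len(kept) == 1

    def test_temperature_outliers_also_removed(self):
        records = [rec(T=t) for t in (300, 301, 302, 303, 800)]
        kept, removed = filter_range_outliers(records)
        assert removed[0].record.temperature == 800

    def test_matches_bruteforce_on_random_fixture(self, rng):
        records = [
            rec(T=float(t), mu=float(v))
            for t, v in zip(
                rng.normal(300, 30, 80), np.exp(rng.normal(0, 1, 80))
            )
        ]
        kept, removed = filter_range_outliers(records)
        # independent brute-force re-implementation with explicit sorting
        for var in ("viscosity", "temperature"):
            vals = sorted(getattr(r, var) for r in records)
            n = len(vals)

            def q(p):
                h = (n - 1) * p
                lo = int(math.floor(h))
                return vals[lo] + (h - lo) * (vals[min(lo + 1, n - 1)] - vals[lo])

            q1, q3 = q(0.25), q(0.75)
            lo_f, hi_f = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
            for r in kept:
                assert lo_f <= getattr(r, var) <= hi_f


class TestDeviationFilter:
    def test_positive_deviation_removed(self):
        records = [rec(T=300, mu=1.00), rec(T=310, mu=1.05)]
        kept, removed = filter_positive_temperature_deviation(records)
        assert len(kept) == 1
        assert removed[0].record.temperature == 310

    def test_decreasing_curve_untouched(self):
        records = [rec(T=t, mu=m) for t, m in [(290, 2.0), (300, 1.5), (310, 1.2)]]
        kept, removed = filter_positive_temperature_deviation(records)
        assert len(kept) == 3 and not removed

    def test_boundary_exactly_at_threshold_kept(self):
        records = [rec(T=300, mu=1.00), rec(T=310, mu=1.02)]
        kept, _ = filter_positive_temperature_deviation(records)
        assert len(kept) == 2  # strictly greater than 0.02 required

    def test_comparison_against_last_retained_point(self):
        # middle point removed; the third compares to the first, not the
        # removed neighbour
        records = [rec(T=300, mu=1.00), rec(T=310, mu=1.50), rec(T=320, mu=1.01)]
        kept, removed = filter_positive_temperature_deviation(records)
        assert [r.temperature for r in kept] == [300, 320]

    def test_compounds_filtered_independently(self):
        records = [rec("CCO", 300, 1.0), rec("CCC", 310, 5.0)]
        kept, _ = filter_positive_temperature_deviation(records)
        assert len(kept) == 2

    def test_post_condition_no_violations_remain(self, rng):
        records = [
            rec(T=float(t), mu=float(v))
            for t, v in zip(rng.uniform(250, 400, 50), rng.uniform(0.5, 3.0, 50))
        ]
        kept, _ = filter_positive_temperature_deviation(records)
        by_T = sorted(kept, key=lambda r: r.temperature)
        for a, b in zip(by_T, by_T[1:]):
            assert b.viscosity - a.viscosity <= 0.02 + 1e-12


class TestLogTransform:
    @pytest.mark.parametrize(
        "mu,expected", [(1.0, 0.0), (0.10, -1.0), (26.52, 1.4236)]
    )
    def test_log10_values(self, mu, expected):
        ds = log_transform_viscosity([rec(mu=mu)])
        assert ds.log_viscosity[0] == pytest.approx(expected, abs=1e-4)

    def test_compound_ids_are_canonical(self):
        ds = log_transform_viscosity([rec("OCC"), rec("CCO")])
        assert ds.compound_ids[0] == ds.compound_ids[1]


class TestCurate:
    def test_empty_input(self):
        ds, report = curate([])
        assert len(ds) == 0 and report.counts_out == 0 and report.reconciles()

    def test_idempotence_on_fixture(self):
        # note: exact idempotence cannot hold for arbitrary data — a
        # single-pass IQR filter shrinks its own fences — but a curated
        # set whose values sit well inside the fences is a fixed point
        from viscml.synthetic import SyntheticConfig, generate_dataset

        records, _ = generate_dataset(SyntheticConfig.curation_fixture(0))
        ds1, _ = curate(records)
        ds2, report2 = curate(ds1.records)
        assert len(ds2) == len(ds1)
        assert report2.counts_in == report2.counts_out
        assert np.allclose(ds2.log_viscosity, ds1.log_viscosity)

    def test_report_reconciles_and_monotone(self, small_dataset):
        dataset, _ = small_dataset
        _, report = curate(dataset.records)
        assert report.reconciles()
        assert report.counts_out <= report.counts_in
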