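"""Synthetic generator: determinism, bookkeeping oracles, planted effects."""

import math

import numpy as np
import pytest

from pvsignals.dedup import deduplicate
from pvsignals.io import write_quarter
from pvsignals.simulate import (DrugSpec, EventSpec, PlantedSignal,
                                SyntheticConfig, default_config,
                                expected_cells, generate)


def small_config(n=1000, seed=5, **kw):
    cfg = SyntheticConfig(
        n_cases=n,
        drugs=[DrugSpec("alphadrug", 0.05, ("ALPHATRADE",)),
               DrugSpec("betadrug", 0.08), DrugSpec("gammadrug", 0.1)],
        events=[EventSpec("Event one", 0.02), EventSpec("Event two", 0.05)],
        seed=seed, **kw)
    return cfg


class TestGenerate:
    def test_zero_cases_empty(self):
        bundles, truth = generate(small_config(n=0))
        assert bundles == [] and truth.n_cases == 0

    def test_invalid_config_rejected(self):
        cfg = small_config()
        cfg.planted = [PlantedSignal("nosuchdrug", "Event one", 10)]
        with pytest.raises(ValueError, match="unknown drug"):
            generate(cfg)

    def test_seed_determinism_byte_identical(self, tmp_path):
        out = {}
        for label in ("a", "b"):
            bundles, _ = generate(small_config(seed=123))
            paths = [write_quarter(b, tmp_path / label / b.quarter)
                     for b in bundles]
            out[label] = [(p, open(f, "rb").read())
                          for d in paths for p, f in sorted(d.items())]
        assert out["a"] == out["b"]

    def test_different_seed_differs(self):
        b1, _ = generate(small_config(seed=1))
        b2, _ = generate(small_config(seed=2))
        assert [b.demo for b in b1] != [b.demo for b in b2]

    def test_row_count_bookkeeping(self):
        bundles, truth = generate(small_config(duplicate_rate=0.3))
        assert sum(len(b.demo) for b in bundles) == truth.n_demo_rows
        assert sum(len(b.drug) for b in bundles) == truth.n_drug_rows
        assert sum(len(b.reac) for b in bundles) == truth.n_reac_rows
        for b in bundles:
            assert b.orphans["drug"] == [] and b.orphans["reac"] == []


class TestDedupRecovery:
    def test_exact_case_count_recovered(self):
        bundles, truth = generate(small_config(duplicate_rate=0.3))
        demo = [r for b in bundles for r in b.demo]
        assert len(demo) > truth.n_cases  # duplicates were injected
        res = deduplicate(demo)
        assert res.n_cases == truth.n_cases == 1000
        assert {r.caseid for r in res.kept_rows} == set(
            truth.drugs_by_case)

    def test_tie_injection_exercises_pid_branch(self):
        bundles, _ = generate(small_config(duplicate_rate=0.5,
                                           tie_rate=1.0, seed=3))
        demo = [r for b in bundles for r in b.demo]
        res = deduplicate(demo)
        rules = {rule for _, rule in res.audit.values()}
        assert "higher-primaryid" in rules


class TestPlantedEffects:
    def test_realized_count_within_three_sigma(self):
        cfg = SyntheticConfig(
            n_cases=50_000,
            drugs=[DrugSpec("alphadrug", 0.01), DrugSpec("betadrug", 0.05)],
            events=[EventSpec("Event one", 0.005),
                    EventSpec("Event two", 0.03)],
            planted=[PlantedSignal("alphadrug", "Event one", 10.0)],
            duplicate_rate=0.0, seed=21)
        _, truth = generate(cfg)
        p = 0.01 * min(1.0, 10.0 * 0.005)
        expect = cfg.n_cases * p
        sd = math.sqrt(cfg.n_cases * p * (1 - p))
        assert abs(truth.pair_a[("alphadrug", "Event one")]
                   - expect) <= 3 * sd

    def test_cap_warning_raised_when_probability_saturates(self):
        cfg = small_config()
        cfg.planted = [PlantedSignal("gammadrug", "Event two", 1000.0)]
        _, truth = generate(cfg)
        assert truth.cap_warning


class TestExpectedCells:
    def test_null_model_gives_unit_ror(self):
        cells = expected_cells(small_config())
        for (a, b, c, d) in cells.values():
            assert (a * d) / (b * c) == pytest.approx(1.0)

    def test_planted_pair_expectation(self):
        cfg = SyntheticConfig(
            n_cases=200_000,
            drugs=[DrugSpec("alphadrug", 0.01)],
            events=[EventSpec("Event one", 0.0005)],
            planted=[PlantedSignal("alphadrug", "Event one", 10.0)])
        (a, _, _, _) = expected_cells(cfg)[("alphadrug", "Event one")]
        assert a == pytest.approx(200_000 * 0.01 * 10 * 0.0005)  # = 10

    def test_expected_ror_monotone_in_rr(self):
        rors = []
        for rr in (1, 2, 5, 10):
            cfg = SyntheticConfig(
                n_cases=100_000,
                drugs=[DrugSpec("alphadrug", 0.01)],
                events=[EventSpec("Event one", 0.001)],
                planted=[PlantedSignal("alphadrug", "Event one",
                                       float(rr))])
            a, b, c, d = expected_cells(cfg)[("alphadrug", "Event one")]
            rors.append((a * d) / (b * c))
        assert all(x < y for x, y in zip(rors, rors[1:]))


def test_default_config_is_valid_and_generates():
    cfg = default_config(n_cases=200, seed=9)
    bundles, truth = generate(cfg)
    assert truth.n_cases == 200
    assert sum(len(b.demo) for b in bundles) >= 200
    # every report carries at least one drug row and one reaction row
    pids = {r.primaryid for b in bundles for r in b.demo}
    drug_pids = {r.primaryid for b in bundles for r in b.drug}
    reac_pids = {r.primaryid for b in bundles for r in b.reac}
    assert pids == drug_pids == reac_pids
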