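"""Generator contracts: catalog structure, grip-prototype geometry, task
timing, Poisson spiking calibration and session determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import graspspace as g
from graspspace.config import GeneratorConfig
from graspspace.synth import (
    UnitSpec,
    build_drive_context,
    make_grip_prototypes,
    sample_timeline,
    sample_trial,
    visual_feature_matrix,
)

SMALL_IDS = {"11", "21", "22", "31", "32", "41", "42"}
ENCLOSE_IDS = {"16", "23", "24", "25", "26", "71", "72", "73", "74", "75", "76"}


class TestCatalog:
    def test_default_has_fifty_unique_conditions(self, catalog):
        assert len(catalog) == 50
        assert catalog["id"].is_unique

    def test_abstract_objects_share_one_grip_class(self, catalog):
        abstract = catalog[catalog["shape"] == "abstract"]
        assert len(abstract) == 6
        assert abstract["grip_class"].nunique() == 1

    def test_parametric_sizes(self, catalog):
        for shape in ("ring", "cube", "sphere", "cylinder_h", "cylinder_v", "bar"):
            fam = catalog[(catalog["shape"] == shape) & (catalog["block"] >= 2)]
            assert sorted(fam["size_mm"]) == [15, 20, 25, 30, 35, 40]

    def test_handle_only_catalog(self):
        handle = g.make_condition_catalog(["handle"])
        assert list(handle["id"]) == ["00", "01"]
        assert handle["shape"].nunique() == 1
        assert handle["grip_class"].nunique() == 2

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown object families"):
            g.make_condition_catalog(["handle", "torus"])


@pytest.fixture(scope="module")
def prototypes(catalog):
    return make_grip_prototypes(catalog, np.random.default_rng(42))


@pytest.fixture(scope="module")
def condition_means(structured_session):
    jspace = g.build_jspace(structured_session)
    frame = pd.DataFrame(jspace.values)
    frame["condition_id"] = jspace.condition_ids
    return frame.groupby("condition_id").mean()


class TestPrototypes:
    def test_abstract_prototypes_identical(self, catalog, prototypes):
        abstract = [c for c in catalog["id"] if c.startswith("9")]
        for cid in abstract[1:]:
            np.testing.assert_array_equal(prototypes[abstract[0]], prototypes[cid])

    def test_handle_grips_are_most_distant(self, catalog, prototypes):
        d = lambda a, b: np.linalg.norm(prototypes[a] - prototypes[b])
        handle_sep = d("00", "01")
        for cid in catalog["id"]:
            if cid not in ("00", "01"):
                assert d("00", cid) < handle_sep

    def test_aperture_monotone_in_size(self, catalog, prototypes):
        for shape in ("ring", "cube", "sphere", "cylinder_h", "cylinder_v", "bar"):
            fam = catalog[(catalog["shape"] == shape) & (catalog["block"] >= 2)]
            fam = fam.sort_values("size_mm")
            apertures = [prototypes[cid][1] for cid in fam["id"]]
            assert np.all(np.diff(apertures) > 0)

    def test_small_objects_mutually_close(self, catalog, prototypes):
        d = lambda a, b: np.linalg.norm(prototypes[a] - prototypes[b])
        within = [d(a, b) for a, b in itertools.combinations(sorted(SMALL_IDS), 2)]
        rest = [c for c in catalog["id"] if c not in SMALL_IDS]
        across = [d(a, b) for a in SMALL_IDS for b in rest]
        assert np.mean(within) < np.mean(across)

    def test_enclosing_grips_cluster(self, catalog, prototypes):
        d = lambda a, b: np.linalg.norm(prototypes[a] - prototypes[b])
        within = [d(a, b) for a, b in itertools.combinations(sorted(ENCLOSE_IDS), 2)]
        rest = [c for c in catalog["id"] if c not in ENCLOSE_IDS]
        across = [d(a, b) for a in ENCLOSE_IDS for b in rest]
        assert np.mean(within) < np.mean(across)
        # the 90 deg wrist-rotation channel carries the offset
        for cid in ENCLOSE_IDS:
            assert prototypes[cid][0] == 90.0

    def test_small_and_big_rings_separated(self, catalog, prototypes):
        d = lambda a, b: np.linalg.norm(prototypes[a] - prototypes[b])
        small, big = ("21", "22"), ("23", "24", "25", "26")
        within_small = d("21", "22")
        across = min(d(a, b) for a in small for b in big)
        assert across > 3 * within_small


class TestTimeline:
    @given(seed=st.integers(0, 10_000))
    def test_timeline_durations(self, seed):
        tl = sample_timeline(GeneratorConfig(), np.random.default_rng(seed))
        times = list(tl.values())
        assert np.all(np.diff(times) > 0)
        assert tl["cue_off"] - tl["cue_on"] == pytest.approx(0.7)
        assert 0.5 <= tl["cue_on"] - tl["fixation_on"] <= 0.8
        assert 0.6 <= tl["go"] - tl["cue_off"] <= 1.0
        assert tl["hold_off"] - tl["hold_on"] == pytest.approx(0.5)


def _single_unit_setup(visual_gain=0.0, motor_gain=0.0, baseline=10.0):
    cfg = GeneratorConfig()
    catalog = g.make_condition_catalog()
    rng = np.random.default_rng(7)
    prototypes = make_grip_prototypes(catalog, rng)
    features, _ = visual_feature_matrix(catalog)
    spec = UnitSpec(
        unit_id=0,
        area="AIP",
        subarray="none",
        baseline_hz=baseline,
        visual_gain=visual_gain,
        motor_gain=motor_gain,
        latency_s=0.05,
        dark_gain=0.6,
        envelope={"fixation": 0.0, "cue": 1.0, "plan": 1.0, "move": 1.0, "hold": 1.0},
        w_visual=rng.standard_normal(features.shape[1]),
        w_motor=rng.standard_normal(27),
    )
    drive = build_drive_context(catalog, prototypes, [spec], cfg)
    return cfg, catalog, prototypes, spec, drive


class TestSpiking:
    def test_poisson_calibration_constant_rate(self):
        """A gain-free 10 Hz unit emits counts inside the exact Poisson 99% CI."""
        from scipy.stats import poisson

        cfg, catalog, prototypes, spec, drive = _single_unit_setup(baseline=10.0)
        rng = np.random.default_rng(123)
        total, duration = 0, 0.0
        for _ in range(500):
            tl, _traj, spikes = sample_trial("31", prototypes, [spec], drive, cfg, rng)
            total += spikes[0].size
            duration += tl["hold_off"]
        lo, hi = poisson.interval(0.99, 10.0 * duration)
        assert lo <= total <= hi

    def test_visual_gain_recovered_from_cue_rates(self):
        """Cue-epoch rate difference between two shapes equals gain * dv."""
        # high baseline so rectification never clips the negative drives
        cfg, catalog, prototypes, spec, drive = _single_unit_setup(
            visual_gain=8.0, baseline=50.0
        )
        ids = list(catalog["id"])
        c1, c2 = "21", "31"  # ring vs cube, same size
        dv = (
            drive.visual_drive[0, ids.index(c1)]
            - drive.visual_drive[0, ids.index(c2)]
        )
        rng = np.random.default_rng(99)
        diffs = []
        for cid in (c1, c2):
            rates = []
            for _ in range(200):
                tl, _traj, spikes = sample_trial(cid, prototypes, [spec], drive, cfg, rng)
                t0, t1 = tl["cue_on"] + spec.latency_s, tl["cue_off"]
                n = np.searchsorted(spikes[0], (t0, t1))
                rates.append((n[1] - n[0]) / (t1 - t0))
            diffs.append(np.mean(rates))
        observed = diffs[0] - diffs[1]
        sem = np.sqrt(2 * 70.0 / 0.65 / 200)  # conservative Poisson s.e.
        assert observed == pytest.approx(dv, abs=4 * sem)

    def test_m1_preset_silent_before_movement(self, structured_session):
        """M1 epoch means (cue vs fixation baseline) are unmodulated."""
        m1 = structured_session.unit_index("M1")
        nspace = g.epoch_means(structured_session, "cue", unit_index=m1)
        assert np.abs(nspace.values.mean(axis=0)).max() < 1.0
        # and no condition could be separated
        result = g.anova_tukey(nspace, int(m1[0]), alpha=0.01)
        assert result.fraction_separated < 0.05

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError, match="gains"):
            _single_unit_setup(visual_gain=-1.0)


class TestSession:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = g.GeneratorConfig(
            unit_counts={"AIP": 3, "F5": 3, "M1": 3}, trials_per_condition=2
        )
        for run in ("a", "b"):
            g.write_session(g.generate_session(cfg, seed=3), tmp_path / run)
        for name in (
            "conditions.csv",
            "units.csv",
            "trials.csv",
            "spikes.csv",
            "kinematics.csv",
            "session.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_default_unit_counts_emulate_recorded_sessions(self):
        total = sum(g.GeneratorConfig().unit_counts.values())
        assert 200 <= total <= 350

    def test_configured_counts_and_repetitions(self, tiny_session):
        assert tiny_session.n_units == 18
        per_cond = tiny_session.trials.groupby("condition_id").size()
        assert (per_cond == 3).all()
        assert tiny_session.n_trials == 150

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="trials_per_condition"):
            g.generate_session(g.GeneratorConfig(trials_per_condition=1), 0)

    def test_null_config_flows_through_downstream_stages(self):
        cfg = g.GeneratorConfig.null(
            unit_counts={"AIP": 4, "F5": 4, "M1": 4}, trials_per_condition=3
        )
        session = g.generate_session(cfg, seed=1)
        nspace = g.epoch_means(session, "hold")
        jspace = g.build_jspace(session)
        transform = g.cda(nspace.values, nspace.condition_ids)
        scores = transform.transform(nspace.values)
        assert np.isfinite(scores).all()
        md = g.modulation_depth(nspace, 0)
        assert md.n_pairs == 50 * 49 // 2
        assert jspace.values.shape == (session.n_trials, 27)


class TestStructureRecovery:
    """PCA of the generated hold-epoch J-space reproduces the prototype
    geometry (distance assertions, not visual inspection)."""

    def test_handle_grips_most_distant_in_jspace(self, condition_means):
        d = lambda a, b: np.linalg.norm(condition_means.loc[a] - condition_means.loc[b])
        sep = d("00", "01")
        for cid in condition_means.index:
            if cid not in ("00", "01"):
                assert d("00", cid) < sep

    def test_small_object_cluster_in_jspace(self, condition_means):
        d = lambda a, b: np.linalg.norm(condition_means.loc[a] - condition_means.loc[b])
        within = [d(a, b) for a, b in itertools.combinations(sorted(SMALL_IDS), 2)]
        rest = [c for c in condition_means.index if c not in SMALL_IDS]
        across = [d(a, b) for a in SMALL_IDS for b in rest]
        assert np.mean(within) < np.mean(across)

    def test_abstract_objects_compact_in_jspace(self, condition_means):
        abstract = [c for c in condition_means.index if c.startswith("9")]
        d = lambda a, b: np.linalg.norm(condition_means.loc[a] - condition_means.loc[b])
        within = max(d(a, b) for a, b in itertools.combinations(abstract, 2))
        rest = [c for c in condition_means.index if not c.startswith("9")]
        across = np.mean([d(a, b) for a in abstract for b in rest])
        # within-cluster spread is pure kinematic noise, far below the
        # distances to conditions with their own prototypes
        assert within < 0.5 * across

    def test_pca_scores_preserve_small_vs_big_ring_split(self, structured_session):
        jspace = g.build_jspace(structured_session)
        result = g.pca(jspace, n_components=5)
        frame = pd.DataFrame(result.scores)
        frame["condition_id"] = jspace.condition_ids
        means = frame.groupby("condition_id").mean()
        d = lambda a, b: np.linalg.norm(means.loc[a] - means.loc[b])
        assert min(d(a, b) for a in ("21", "22") for b in ("23", "24", "25", "26")) > d(
            "21", "22"
        )
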