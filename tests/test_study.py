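"""Transfer-study orchestration: tasks, updating, sweeps, reports."""

import numpy as np
import pytest

from nirtransfer import (
    StudyConfig,
    StudyReport,
    default_four_brand_study,
    default_grid,
    pooled_model_experiment,
    run_full_study,
    run_transfer_task,
    run_updated_sweep,
    update_domains,
)
from nirtransfer.io import SpectralDataset
from nirtransfer.simulate import (
    BrandDesign,
    DomainShift,
    make_component_library,
    synthesize_dataset,
)

GRID = default_grid(10_000, 4_000, 40)  # 151 points: fast but structured


def tiny_brand(brand, offset, seed, n=40, variant=None):
    lib = make_component_library(GRID, 99, silk_variants={"a": 0.03, "b": 0.03})
    design = BrandDesign(
        brand, n, {"tobacco_silk": (70, 100), "cut_stem": (0, 30)}, silk_variant=variant
    )
    shift = DomainShift(additive_offset=offset, noise_sd=1e-3)
    return synthesize_dataset(lib, design, shift, seed, id_prefix=brand, nuisance_sd=0.05)


@pytest.fixture(scope="module")
def two_brands():
    return {
        "A": tiny_brand("A", 0.02, seed=1, variant="a"),
        "B": tiny_brand("B", -0.02, seed=2, variant="b"),
    }


FAST = StudyConfig(k_folds=5, max_lv=10, tca_dim=15)


class TestRunTransferTask:
    def test_self_transfer_direct_rmsep_equals_rmsec(self, two_brands):
        ds = two_brands["A"]
        res = run_transfer_task(ds, ds, "direct", FAST, seed=0)
        assert res.rmsep == pytest.approx(res.rmsec, abs=1e-9)

    @pytest.mark.parametrize("method", ["direct", "tca", "coral"])
    def test_self_transfer_sanity_every_method(self, two_brands, method):
        ds = two_brands["A"]
        res = run_transfer_task(ds, ds, method, FAST, seed=0)
        assert res.rmsep <= res.rmsec + 1e-6

    def test_tca_on_identical_domains_matches_direct(self, two_brands):
        # with no domain shift the TCA projection is an orthogonal map
        # (scaled) of the data span, so predictions coincide with direct's
        ds = two_brands["A"]
        cfg = StudyConfig(k_folds=5, max_lv=10, tca_dim=len(ds) - 1)  # m >= data rank
        direct = run_transfer_task(ds, ds, "direct", cfg, seed=0)
        tca = run_transfer_task(ds, ds, "tca", cfg, seed=0)
        assert tca.rmsep == pytest.approx(direct.rmsep, abs=1e-6)

    def test_result_carries_counts_and_task_metadata(self, two_brands):
        res = run_transfer_task(two_brands["A"], two_brands["B"], "tca", FAST, seed=3)
        assert res.n_source == 40 and res.n_target_predicted == 40
        assert res.task.source_brand == "A" and res.task.target_brand == "B"
        assert res.chosen_n_latent >= 1
        assert np.isfinite([res.r_c, res.rmsec, res.r_p, res.rmsep, res.mae]).all()

    def test_grid_mismatch_rejected(self, two_brands):
        other = tiny_brand("C", 0.0, seed=3)
        shrunk = SpectralDataset(
            other.wavenumbers[:-1], other.absorbance[:, :-1], other.target,
            other.brand, other.sample_id,
        )
        with pytest.raises(ValueError, match="grid"):
            run_transfer_task(two_brands["A"], shrunk, "direct", FAST)

    def test_partial_sample_overlap_rejected_as_leakage(self, two_brands):
        src = two_brands["A"]
        mixed = src.take(np.arange(10))  # shares ids with src but is not src
        with pytest.raises(ValueError, match="leakage"):
            run_transfer_task(src, mixed, "direct", FAST)


class TestUpdateDomains:
    def test_zero_fraction_is_identity(self, two_brands):
        src, tgt = update_domains(two_brands["A"], two_brands["B"], 0.0)
        assert src is two_brands["A"] and tgt is two_brands["B"]

    def test_ten_percent_of_two_hundred_moves_twenty(self):
        src = tiny_brand("S", 0.0, seed=4, n=50)
        tgt = tiny_brand("T", 0.0, seed=5, n=200)
        upd, red = update_domains(src, tgt, 0.10)
        assert len(upd) == 70 and len(red) == 180

    @pytest.mark.parametrize("mode", ["systematic", "random"])
    @pytest.mark.parametrize("fraction", [0.01, 0.05, 0.10])
    def test_conservation_and_disjointness(self, two_brands, mode, fraction):
        src, tgt = two_brands["A"], two_brands["B"]
        upd, red = update_domains(src, tgt, fraction, selection_mode=mode, seed=1)
        assert len(upd) + len(red) == len(src) + len(tgt)
        assert not set(upd.sample_id) & set(red.sample_id)
        moved = set(upd.sample_id) - set(src.sample_id)
        assert len(moved) == int(round(fraction * len(tgt)))

    def test_systematic_selection_covers_target_range(self):
        tgt = tiny_brand("T", 0.0, seed=6, n=100)
        src = tiny_brand("S", 0.0, seed=7, n=50)
        upd, _ = update_domains(src, tgt, 0.10, selection_mode="systematic")
        moved_y = upd.target[len(src):]
        assert moved_y.min() == tgt.target.min() and moved_y.max() == tgt.target.max()

    def test_random_selection_deterministic_per_seed(self, two_brands):
        a = update_domains(*two_brands.values(), 0.1, selection_mode="random", seed=5)
        b = update_domains(*two_brands.values(), 0.1, selection_mode="random", seed=5)
        assert a[0].sample_id.tolist() == b[0].sample_id.tolist()

    def test_fraction_leaving_too_few_targets_rejected(self):
        src = tiny_brand("S", 0.0, seed=8, n=40)
        tgt = tiny_brand("T", 0.0, seed=9, n=4)
        with pytest.raises(ValueError, match="too few"):
            update_domains(src, tgt, 0.45)
        with pytest.raises(ValueError, match="fraction"):
            update_domains(src, tgt, 0.6)


class TestSweep:
    def test_sweep_composes_update_then_task(self, two_brands):
        src, tgt = two_brands["A"], two_brands["B"]
        swept = run_updated_sweep(src, tgt, "direct", [0.05], FAST, seed=2)[0]
        upd, red = update_domains(src, tgt, 0.05, selection_mode="systematic", seed=2)
        manual = run_transfer_task(upd, red, "direct", FAST, seed=2, updating_fraction=0.05)
        assert swept.rmsep == manual.rmsep and swept.rmsec == manual.rmsec

    def test_one_result_per_fraction(self, two_brands):
        fractions = [f / 100 for f in range(1, 11)]
        results = run_updated_sweep(*two_brands.values(), "direct", fractions, FAST, seed=0)
        assert [r.task.updating_fraction for r in results] == fractions
        assert all(r.n_source + r.n_target_predicted == 80 for r in results)


class TestPooledAndFullStudy:
    def test_pooled_merges_and_splits_two_to_one(self, two_brands):
        res = pooled_model_experiment(two_brands, FAST)
        n = sum(len(ds) for ds in two_brands.values())
        assert res.n_source + res.n_target_predicted == n
        assert res.n_target_predicted == n // 3

    def test_pooled_rejects_too_small_merge(self):
        tiny = tiny_brand("S", 0.0, seed=10, n=2)
        with pytest.raises(ValueError):
            pooled_model_experiment({"S": tiny}, FAST)

    def test_full_study_structure_and_determinism(self, two_brands):
        cfg = StudyConfig(
            k_folds=5, max_lv=8, tca_dim=15,
            sweep_pairs=(("A", "B"),), sweep_methods=("direct",),
            sweep_fractions=(0.05, 0.10), master_seed=3,
        )
        report = run_full_study(two_brands, cfg)
        assert len(report.tasks) == 2 * 3       # 2 ordered pairs x 3 methods
        assert len(report.sweeps) == 2
        again = run_full_study(two_brands, cfg)
        assert report.to_json() == again.to_json()

    def test_report_serialization_lossless(self, two_brands):
        cfg = StudyConfig(k_folds=5, max_lv=8, tca_dim=15,
                          sweep_pairs=(), sweep_methods=(), master_seed=1)
        report = run_full_study(two_brands, cfg)
        back = StudyReport.from_json(report.to_json())
        assert back.to_json() == report.to_json()
        for a, b in zip(report.tasks, back.tasks):
            assert a.rmsep == b.rmsep and a.task.label == b.task.label

    def test_report_table_layout(self, two_brands):
        cfg = StudyConfig(k_folds=5, max_lv=8, tca_dim=15,
                          sweep_pairs=(), sweep_methods=(), master_seed=1)
        table = run_full_study(two_brands, cfg).to_table()
        assert list(table.columns[:8]) == [
            "task", "method", "updating_fraction", "R_c", "RMSEC (%)",
            "R_p", "RMSEP (%)", "MAE (%)",
        ]
        assert len(table) == 7  # pooled + 6 task rows


def test_default_study_has_twelve_ordered_pairs(default_study):
    brands = sorted(default_study)
    pairs = [(s, t) for s in brands for t in brands if s != t]
    assert len(pairs) == 12


def test_sweep_plot_draws_one_line_per_pair_method(two_brands_module_hack=None):
    import matplotlib

    matplotlib.use("Agg")
    cfg = StudyConfig(
        k_folds=5, max_lv=8, tca_dim=15,
        sweep_pairs=(("A", "B"),), sweep_methods=("direct",),
        sweep_fractions=(0.05, 0.10), master_seed=0,
    )
    brands = {
        "A": tiny_brand("A", 0.02, seed=21, variant="a"),
        "B": tiny_brand("B", -0.02, seed=22, variant="b"),
    }
    ax = run_full_study(brands, cfg).plot_sweeps()
    assert len(ax.lines) == 1
    assert len(ax.lines[0].get_xdata()) == 2
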