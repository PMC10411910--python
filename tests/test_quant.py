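"""Quantification estimators: normalization, counting, classification, noise stats."""

import numpy as np
import pandas as pd
import pytest

from subpoisson.quant import (
    FilterConfig,
    cell_volume,
    classify_nascent,
    count_cells,
    filter_cells,
    noise_summary,
    normalize_intensities,
    nuc_cyto_covariance,
    pivot_counts,
    size_corrected_fano,
    sliding_window_fano,
)


def spot_frame(rows):
    return pd.DataFrame(rows, columns=["image_id", "cell_id", "compartment", "intensity"])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_divides_by_per_image_cytoplasmic_median(self):
        spots = spot_frame([
            ("i1", 1, "cytoplasmic", 2.0),
            ("i1", 1, "cytoplasmic", 4.0),
            ("i1", 2, "cytoplasmic", 6.0),
            ("i1", 2, "nuclear", 12.0),
            ("i2", 1, "cytoplasmic", 10.0),  # second image, different gain
        ])
        out = normalize_intensities(spots)
        np.testing.assert_allclose(
            out["normalized_intensity"].to_numpy(), [0.5, 1.0, 1.5, 3.0, 1.0]
        )
        # per-image median of cytoplasmic normalized intensities is exactly 1
        med = (out[out["compartment"] == "cytoplasmic"]
               .groupby("image_id")["normalized_intensity"].median())
        assert (med == 1.0).all()

    def test_image_without_cytoplasmic_spots_dropped_with_warning(self):
        spots = spot_frame([
            ("i1", 1, "cytoplasmic", 2.0),
            ("i2", 1, "nuclear", 3.0),
        ])
        with pytest.warns(UserWarning, match="i2"):
            out = normalize_intensities(spots)
        assert set(out["image_id"]) == {"i1"}

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            normalize_intensities(spot_frame([("i1", 1, "cytoplasmic", 0.0)]))


# ---------------------------------------------------------------------------
# counting methods
# ---------------------------------------------------------------------------

def example_table():
    """Cell 1: four ordinary cytoplasmic spots and one bright nuclear spot;
    cell 2 supplies enough ordinary spots to pin the 95th-percentile threshold."""
    rows = [("i1", 1, "cytoplasmic", v) for v in (0.8, 0.9, 1.0, 1.1)]
    rows += [("i1", 2, "cytoplasmic", 1.0)] * 15 + [("i1", 2, "cytoplasmic", 2.0)]
    rows += [("i1", 1, "nuclear", 3.2)]
    df = spot_frame(rows)
    df["normalized_intensity"] = df["intensity"]
    return df


class TestCounting:
    def test_spot_counts_every_spot_once(self):
        counts = count_cells(example_table(), method="spot")
        c = counts.set_index(["cell_id", "compartment"])["count"]
        assert c[(1, "cytoplasmic")] == 4
        assert c[(1, "nuclear")] == 1
        assert counts["count"].dtype.kind == "i"

    def test_intensity_sums_normalized_intensities(self):
        counts = count_cells(example_table(), method="intensity")
        c = counts.set_index(["cell_id", "compartment"])["count"]
        assert c[(1, "cytoplasmic")] == pytest.approx(0.8 + 0.9 + 1.0 + 1.1)
        assert c[(1, "nuclear")] == pytest.approx(3.2)

    def test_hybrid_counts_dim_spots_once_and_bright_by_intensity(self):
        # 95th percentile of the 20 cytoplasmic intensities is ~1.145, so the
        # dim spots count 1 each while the 2.0 and 3.2 spots count as intensity
        counts = count_cells(example_table(), method="hybrid")
        c = counts.set_index(["cell_id", "compartment"])["count"]
        assert c[(1, "cytoplasmic")] == pytest.approx(4.0)
        assert c[(1, "nuclear")] == pytest.approx(3.2)
        assert c[(2, "cytoplasmic")] == pytest.approx(15.0 + 2.0)

    def test_hybrid_at_least_spot_count(self):
        rng = np.random.default_rng(0)
        df = spot_frame([
            ("i1", int(c), "cytoplasmic", v)
            for c, v in zip(rng.integers(0, 50, 500),
                            rng.lognormal(0, 0.3, 500))
        ])
        df = normalize_intensities(df)
        hybrid = count_cells(df, method="hybrid").set_index("cell_id")["count"]
        spot = count_cells(df, method="spot").set_index("cell_id")["count"]
        assert (hybrid >= spot.loc[hybrid.index] - 1e-12).all()

    def test_threshold_is_per_sample(self):
        # replicate r2 has a 10x gain; its threshold must come from its own spots
        rows = [("i1", 1, "cytoplasmic", v) for v in np.linspace(0.5, 1.5, 20)]
        rows += [("i2", 1, "cytoplasmic", 10 * v) for v in np.linspace(0.5, 1.5, 20)]
        df = spot_frame(rows)
        df["replicate_id"] = np.repeat(["r1", "r2"], 20)
        df["normalized_intensity"] = df["intensity"]
        counts = count_cells(df, method="hybrid")
        c = counts.set_index("image_id")["count"]
        # within each sample only the single top spot exceeds its own 95th pct
        assert c["i1"] == pytest.approx(19 + 1.5)
        assert c["i2"] == pytest.approx(19 + 15.0)

    def test_cells_argument_fills_zero_counts(self):
        cells = pd.DataFrame({"image_id": ["i1", "i1"], "cell_id": [1, 3]})
        counts = count_cells(example_table(), method="spot", cells=cells)
        c = counts.set_index(["cell_id", "compartment"])["count"]
        assert c[(3, "nuclear")] == 0 and c[(3, "cytoplasmic")] == 0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="unknown counting method"):
            count_cells(example_table(), method="psf")
        bare = example_table().drop(columns="normalized_intensity")
        with pytest.raises(ValueError, match="normalize_intensities"):
            count_cells(bare, method="hybrid")

    def test_pivot_counts_fills_missing_compartment(self):
        counts = pd.DataFrame({
            "image_id": ["i1"], "cell_id": [1],
            "compartment": ["nuclear"], "count": [2],
        })
        wide = pivot_counts(counts)
        assert wide.loc[0, "nuclear_count"] == 2
        assert wide.loc[0, "cytoplasmic_count"] == 0


# ---------------------------------------------------------------------------
# nascent classification
# ---------------------------------------------------------------------------

def bimodal_spots(n_near=60, n_far=60, seed=0, image_id="i1"):
    rng = np.random.default_rng(seed)
    near = 0.15 * np.exp(rng.normal(0, 0.25, n_near))
    far = 1.5 * np.exp(rng.normal(0, 0.25, n_far))
    return pd.DataFrame({
        "image_id": image_id,
        "cell_id": np.arange(n_near + n_far),
        "compartment": "nuclear",
        "nearest_ts_distance": np.concatenate([near, far]),
    })


class TestClassifyNascent:
    def test_bimodal_distances_split_accurately(self):
        spots = bimodal_spots()
        res = classify_nascent(spots)
        truth = np.array(["nascent"] * 60 + ["mature_nuclear"] * 60)
        accuracy = (res.labels.to_numpy() == truth).mean()
        assert accuracy >= 0.99
        assert 0.2 < res.cutoffs["i1"] < 1.0

    def test_kde_backend_agrees_on_well_separated_modes(self):
        spots = bimodal_spots(seed=1)
        otsu = classify_nascent(spots, backend="otsu")
        kde = classify_nascent(spots, backend="kde")
        assert (otsu.labels == kde.labels).mean() >= 0.98

    def test_unimodal_falls_back_with_warning(self):
        rng = np.random.default_rng(2)
        spots = pd.DataFrame({
            "image_id": "i1", "cell_id": np.arange(50), "compartment": "nuclear",
            "nearest_ts_distance": 1.5 * np.exp(rng.normal(0, 0.2, 50)),
        })
        with pytest.warns(UserWarning, match="unimodal"):
            res = classify_nascent(spots)
        assert res.cutoffs["i1"] == 0.6
        assert (res.labels == "mature_nuclear").all()

    def test_ts_outside_nucleus_expand_vs_filter(self):
        spots = bimodal_spots(seed=3)
        extra = pd.DataFrame({
            "image_id": ["i1"], "cell_id": [999], "compartment": ["cytoplasmic"],
            "nearest_ts_distance": [0.1],  # cytoplasmic spot right at a TS
        })
        spots = pd.concat([spots, extra], ignore_index=True)
        expand = classify_nascent(spots, ts_outside_mode="expand")
        assert expand.labels.iloc[-1] == "nascent"
        filt = classify_nascent(spots, ts_outside_mode="filter")
        assert filt.labels.iloc[-1] == "cytoplasmic"
        assert ("i1", 999) in filt.excluded_cells

    def test_distances_computed_from_ts_table(self):
        spots = pd.DataFrame({
            "image_id": ["i1"] * 2, "cell_id": [1, 1], "compartment": ["nuclear"] * 2,
            "x": [1.0, 0.3], "y": [0.0, 0.0], "z": [0.0, 0.4],
        })
        ts = pd.DataFrame({"image_id": ["i1"], "cell_id": [1],
                           "x": [0.0], "y": [0.0], "z": [0.0]})
        with pytest.warns(UserWarning):  # only 2 spots -> fallback cutoff
            res = classify_nascent(spots, ts_spots=ts)
        assert list(res.labels) == ["mature_nuclear", "nascent"]

    def test_requires_distance_information(self):
        with pytest.raises(ValueError, match="nearest_ts_distance"):
            classify_nascent(pd.DataFrame({"image_id": [], "cell_id": [],
                                           "compartment": []}))

    def test_rejects_bad_modes(self):
        spots = bimodal_spots()
        with pytest.raises(ValueError):
            classify_nascent(spots, backend="gmm")
        with pytest.raises(ValueError):
            classify_nascent(spots, ts_outside_mode="drop")


# ---------------------------------------------------------------------------
# cell filters and geometry
# ---------------------------------------------------------------------------

def cell_frame(lengths, widths=None, **extra):
    n = len(lengths)
    df = pd.DataFrame({
        "image_id": "i1", "cell_id": np.arange(n),
        "length": lengths, "width": 3.6 if widths is None else widths,
    })
    for k, v in extra.items():
        df[k] = v
    return df


class TestFilters:
    def test_length_outlier_removed_with_reason(self):
        lengths = np.concatenate([np.full(50, 10.0) + np.linspace(-1, 1, 50), [30.0]])
        cells = cell_frame(lengths)
        kept, log = filter_cells(cells)
        assert len(kept) == 50
        assert len(log) == 1
        assert "SD" in log.loc[0, "rule"]

    def test_length_rule_not_recomputed_after_exclusion(self):
        # one extreme outlier inflates the SD; a milder cell survives because
        # the rule uses the input sample's moments, applied once
        lengths = np.concatenate([np.full(60, 10.0) + np.linspace(-0.5, 0.5, 60),
                                  [14.0, 60.0]])
        kept, log = filter_cells(cell_frame(lengths))
        assert 14.0 in kept["length"].to_numpy()
        assert 60.0 not in kept["length"].to_numpy()

    def test_length_rule_is_per_replicate(self):
        # a length typical for rep2 but extreme for rep1 must use rep2's moments
        l1 = np.full(40, 8.0) + np.linspace(-0.5, 0.5, 40)
        l2 = np.full(40, 14.0) + np.linspace(-0.5, 0.5, 40)
        cells = cell_frame(np.concatenate([l1, l2]),
                           replicate_id=np.repeat(["r1", "r2"], 40))
        kept, log = filter_cells(cells)
        assert len(kept) == 80 and len(log) == 0

    def test_legacy_width_and_length_bounds(self):
        cells = cell_frame([10.0, 10.0, 17.0], widths=[3.6, 4.5, 3.6])
        rules = FilterConfig(length_sd=None, width_range=(1.5, 4.0), max_length=16.0)
        kept, log = filter_cells(cells, rules)
        assert list(kept["cell_id"]) == [0]
        assert set(log["rule"]) == {"width outside [1.5, 4.0] um", "length > 16.0 um"}

    def test_ts_label_qc(self):
        cells = cell_frame([10.0] * 4, n_gfp_spots=[1, 2, 0, 3],
                           cytoplasmic_gfp=[False, True, False, False])
        rules = FilterConfig(length_sd=None, require_ts_labels=True)
        kept, log = filter_cells(cells, rules)
        assert list(kept["cell_id"]) == [0]
        assert len(log) == 3


class TestCellVolume:
    def test_sphere_limit(self):
        assert cell_volume(4.0, 4.0) == pytest.approx(4.0 / 3.0 * np.pi * 8.0)

    def test_capped_cylinder(self):
        # L=10, w=4: pi*2^2*6 + (4/3)*pi*2^3
        assert cell_volume(10.0, 4.0) == pytest.approx(24 * np.pi + 32 * np.pi / 3)

    def test_scaling(self):
        assert cell_volume(20.0, 8.0) == pytest.approx(8 * cell_volume(10.0, 4.0))

    def test_vectorized_and_validated(self):
        v = cell_volume(np.array([10.0, 4.0]), np.array([4.0, 4.0]))
        assert v.shape == (2,)
        with pytest.raises(ValueError):
            cell_volume(3.0, 4.0)  # length < width


# ---------------------------------------------------------------------------
# size-corrected Fano factor
# ---------------------------------------------------------------------------

class TestSizeCorrectedFano:
    def test_size_independent_counts_keep_raw_fano(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4.0, 3000)
        sizes = rng.uniform(7, 14, 3000)
        res = size_corrected_fano(counts, sizes, n_boot=500, seed=0)
        assert res.value == pytest.approx(res.raw_fano, abs=0.05)
        assert abs(res.slope) < 0.05

    def test_removes_linear_size_trend(self):
        # Poisson counts with mean proportional to size: raw Fano > 1 from the
        # size mixture, corrected Fano ~ 1
        rng = np.random.default_rng(1)
        sizes = rng.uniform(7, 14, 5000)
        counts = rng.poisson(0.5 * sizes)
        res = size_corrected_fano(counts, sizes, n_boot=2000, seed=1)
        assert res.raw_fano > 1.1
        assert res.value == pytest.approx(1.0, abs=0.08)
        assert res.ci[0] < res.value < res.ci[1]
        assert res.slope == pytest.approx(0.5, abs=0.05)

    def test_invariant_to_size_rescaling(self):
        rng = np.random.default_rng(2)
        sizes = rng.uniform(7, 14, 500)
        counts = rng.poisson(0.5 * sizes)
        a = size_corrected_fano(counts, sizes, n_boot=200, seed=3)
        b = size_corrected_fano(counts, sizes * 7.0, n_boot=200, seed=3)
        assert b.value == pytest.approx(a.value, rel=1e-9)
        assert b.slope == pytest.approx(a.slope / 7.0, rel=1e-9)

    def test_constant_counts_give_zero(self):
        sizes = np.linspace(7, 14, 100)
        res = size_corrected_fano(np.full(100, 3.0), sizes, n_boot=100, seed=0)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_sizes_fall_back_to_raw(self):
        counts = np.random.default_rng(4).poisson(3.0, 100)
        with pytest.warns(UserWarning, match="degenerate"):
            res = size_corrected_fano(counts, np.full(100, 10.0), n_boot=100)
        assert res.value == res.raw_fano
        assert np.isnan(res.se)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            size_corrected_fano(np.arange(10.0), np.linspace(7, 14, 10), n_boot=50)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            size_corrected_fano(np.arange(10.0), np.arange(9.0))


# ---------------------------------------------------------------------------
# sliding-window Fano profile
# ---------------------------------------------------------------------------

class TestSlidingWindow:
    def test_profile_flat_for_size_scaled_poisson(self):
        rng = np.random.default_rng(0)
        lengths = np.sort(rng.uniform(7, 14, 6000))
        counts = rng.poisson(0.5 * lengths)
        prof = sliding_window_fano(counts, lengths)
        assert len(prof) > 20
        # within each narrow window counts are ~Poisson -> Fano ~ 1
        assert prof["fano"].mean() == pytest.approx(1.0, abs=0.05)
        # mean per window follows the size scaling
        lo, hi = prof.iloc[0], prof.iloc[-1]
        assert hi["mean"] > lo["mean"]

    def test_run_of_exactly_min_consecutive_windows_is_retained(self):
        # 'bi' stratum: pooled >= 30 cells and >= 6 consecutive windows.
        # Equally spaced lengths over [0, 1.5] give exactly 6 windows of 40.
        lengths = np.arange(0.0, 1.5, 1.0 / 40.0)
        counts = np.resize([1.0, 3.0], lengths.size)
        prof = sliding_window_fano(counts, lengths, nucleation="bi")
        assert len(prof) == 6
        assert (prof["n_cells"] >= 30).all()

    def test_shorter_run_is_dropped(self):
        # same density but only 5 windows: below the 6-window minimum run
        lengths = np.arange(0.0, 1.4, 1.0 / 40.0)
        counts = np.resize([1.0, 3.0], lengths.size)
        prof = sliding_window_fano(counts, lengths, nucleation="bi")
        assert prof.empty

    def test_sparse_windows_are_dropped(self):
        # 20 cells per window is below every pooled threshold
        lengths = np.arange(0.0, 4.0, 1.0 / 20.0)
        counts = np.resize([1.0, 3.0], lengths.size)
        assert sliding_window_fano(counts, lengths, nucleation="all").empty

    def test_replicate_threshold_is_lower_than_pooled(self):
        # 45 cells per window: below the pooled minimum (50) for 'all' but
        # above the single-replicate minimum (40)
        lengths = np.arange(0.0, 4.0, 1.0 / 45.0)
        counts = np.resize([1.0, 3.0], lengths.size)
        assert sliding_window_fano(counts, lengths, nucleation="all",
                                   population="pooled").empty
        rep = sliding_window_fano(counts, lengths, nucleation="all",
                                  population="replicate")
        assert len(rep) >= 20

    def test_validation_and_empty_input(self):
        with pytest.raises(ValueError):
            sliding_window_fano([1.0], [1.0], population="both")
        with pytest.raises(ValueError):
            sliding_window_fano([1.0], [1.0], nucleation="tri")
        with pytest.raises(ValueError):
            sliding_window_fano([1.0, 2.0], [1.0])
        assert sliding_window_fano([], []).empty


# ---------------------------------------------------------------------------
# nuclear-cytoplasmic covariance
# ---------------------------------------------------------------------------

class TestCovariance:
    def test_identical_vectors_give_variance(self):
        x = np.random.default_rng(0).poisson(4.0, 200).astype(float)
        res = nuc_cyto_covariance(x, x, n_boot=200, seed=0)
        assert res.covariance == pytest.approx(x.var(ddof=1))

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(1)
        res = nuc_cyto_covariance(rng.poisson(2.0, 3000), rng.poisson(4.0, 3000),
                                  n_boot=1000, seed=1)
        assert abs(res.covariance) < 3.5 * res.se
        assert res.ci[0] < 0 < res.ci[1]

    def test_size_partialled_covariance_removes_shared_trend(self):
        rng = np.random.default_rng(2)
        sizes = rng.uniform(7, 14, 4000)
        nuc = rng.poisson(0.3 * sizes)
        cyt = rng.poisson(0.6 * sizes)
        res = nuc_cyto_covariance(nuc, cyt, sizes=sizes, n_boot=1000, seed=2)
        assert res.covariance > 0.1              # shared size trend
        assert res.partial_covariance is not None
        assert res.partial_ci[0] < 0 < res.partial_ci[1]  # nothing left after

    def test_small_sample_flagged(self):
        with pytest.warns(UserWarning, match="low-precision"):
            res = nuc_cyto_covariance(np.arange(10.0), np.arange(10.0), n_boot=50)
        assert res.low_n

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            nuc_cyto_covariance(np.arange(10.0), np.arange(9.0))


def test_noise_summary_bundle():
    rng = np.random.default_rng(3)
    sizes = rng.uniform(7, 14, 500)
    nuc = rng.poisson(0.2 * sizes)
    cyt = rng.poisson(0.4 * sizes)
    summ = noise_summary("demo", "cytoplasmic", cyt, sizes,
                         paired_counts=nuc, n_boot=300, seed=3)
    d = summ.to_dict()
    assert d["n_cells"] == 500
    assert d["fano_ci_low"] < d["size_corrected_fano"] < d["fano_ci_high"]
    assert d["cov_nuc_cyto"] is not None
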