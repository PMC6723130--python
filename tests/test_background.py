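"""Background fitting, confidence intervals, filtering and spectra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umivar.background import (
    BackgroundDistribution,
    BackgroundModel,
    ROUTE_EDGE,
    ROUTE_GENERIC,
    ROUTE_POSITIONAL,
    SubKey,
    alpha_from_nines,
    build_generic_background,
    build_position_background,
    ci_endpoints,
    filter_variants,
    fit_background_distribution,
    significant_call_counts,
    spectrum,
)
from umivar.errors import ConfigError, InsufficientControlsError

# independently computed with R: mean/sd/qt on
# v = c(0.001, 0.002, 0.0015, 0.0012, 0.0008)
R_MEAN = 0.0013
R_SD = 0.000469041575982
R_HIGH_99 = 0.00345951191443
R_HIGH_95 = 0.00260226818777
# qt(0.975, 4) applied to loc=0.001, scale=5e-4
R_HIGH_DF4 = 0.0023882225526

VAFS = np.array([0.001, 0.002, 0.0015, 0.0012, 0.0008])


def _calls(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "probe_id", "offset", "ref", "alt",
                 "supporting_captures", "covering_captures", "vaf", "context"],
    )


def _call(pos, ref, alt, vaf, context, chrom="chr1", probe="p1"):
    return (chrom, pos, probe, 0, ref, alt, max(int(vaf * 1e4), 5), 10_000,
            vaf, context)


class TestTInterval:
    def test_matches_r_quantile_computation(self):
        dist = fit_background_distribution(VAFS, alpha=0.99, outlier_drop=0)
        assert dist.location == pytest.approx(R_MEAN, rel=1e-9)
        assert dist.scale == pytest.approx(R_SD, rel=1e-9)
        assert dist.high == pytest.approx(R_HIGH_99, rel=1e-9)
        assert dist.low == 0.0  # floored at zero

    def test_requery_at_different_alpha(self):
        dist = fit_background_distribution(VAFS, alpha=0.99, outlier_drop=0)
        _, high = ci_endpoints(dist, 0.95)
        assert high == pytest.approx(R_HIGH_95, rel=1e-9)

    def test_df4_textbook_interval(self):
        dist = BackgroundDistribution(
            n_controls=5, location=0.001, scale=5e-4, low=0.0, high=0.0
        )
        low, high = ci_endpoints(dist, 0.95)
        assert high == pytest.approx(R_HIGH_DF4, rel=1e-9)
        assert low == 0.0

    def test_degenerate_scale_collapses_interval(self):
        dist = fit_background_distribution(
            np.full(5, 0.001), alpha=0.99, outlier_drop=0
        )
        assert dist.scale == 0.0
        assert (dist.low, dist.high) == (0.001, 0.001)
        assert ci_endpoints(dist, 0.9999) == (0.001, 0.001)

    def test_alpha_domain_errors(self):
        dist = fit_background_distribution(VAFS, alpha=0.99)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ConfigError):
                ci_endpoints(dist, bad)

    @given(
        alphas=st.tuples(st.floats(0.5, 0.999), st.floats(0.5, 0.999)),
        scale=st.floats(1e-6, 1e-2),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nesting_property(self, alphas, scale):
        a1, a2 = sorted(alphas)
        dist = BackgroundDistribution(
            n_controls=8, location=1e-3, scale=scale, low=0.0, high=0.0
        )
        low1, high1 = ci_endpoints(dist, a1)
        low2, high2 = ci_endpoints(dist, a2)
        assert low2 <= low1 and high1 <= high2
        if a1 < a2:
            assert high1 < high2

    def test_outlier_drop_removes_highest(self):
        dist = fit_background_distribution(
            np.array([0.0, 0.0, 0.001, 0.3]), alpha=0.99, outlier_drop=1
        )
        assert dist.n_controls == 3
        assert max(dist.vafs) == 0.001

    def test_alpha_from_nines(self):
        assert alpha_from_nines(1) == pytest.approx(0.9)
        assert alpha_from_nines(3) == pytest.approx(0.999)
        assert alpha_from_nines(10) == pytest.approx(1 - 1e-10)


@pytest.fixture(scope="module")
def control_calls(sim_panel_module):
    """Three hand-built control call sets on the session sim panel."""
    panel = sim_panel_module
    probe = panel.probes[0]
    pos_hot = probe.start + 40
    ref_hot = probe.region_seq[40]
    alt_hot = "ACGT"[("ACGT".index(ref_hot) + 1) % 4]
    ctx_hot = probe.region_seq[39:42]
    pos_het = probe.start + 80
    ref_het = probe.region_seq[80]
    alt_het = "ACGT"[("ACGT".index(ref_het) + 1) % 4]
    ctx_het = probe.region_seq[79:82]
    sets = []
    for vaf in (8e-4, 1.1e-3, 9e-4):
        sets.append(
            _calls([
                _call(pos_hot, ref_hot, alt_hot, vaf, ctx_hot),
                _call(pos_het, ref_het, alt_het, 0.5, ctx_het),
            ])
        )
    return sets, SubKey(probe.chrom, pos_hot, ref_hot, alt_hot)


@pytest.fixture(scope="module")
def sim_panel_module():
    from umivar.experiments import synthetic_panel

    return synthetic_panel(n_probes=1, region_length=126, seed=2024)


class TestBuildBackground:
    def test_positional_key_fitted_without_outlier_drop(
        self, control_calls, sim_panel_module
    ):
        sets, hot = control_calls
        model = build_position_background(
            sets, sim_panel_module, alpha=0.99, outlier_drop=0
        )
        dist = model.positional[hot]
        assert dist.n_controls == 3
        assert dist.location == pytest.approx(np.mean([8e-4, 1.1e-3, 9e-4]))

    def test_het_vafs_excluded_by_ceiling(self, control_calls, sim_panel_module):
        sets, hot = control_calls
        model = build_position_background(
            sets, sim_panel_module, alpha=0.99, outlier_drop=0
        )
        het_keys = [k for k in model.positional if k.pos == hot.pos + 40]
        assert not het_keys  # 0.5 VAFs dropped, so the key never appears

    def test_unobserved_key_absent(self, control_calls, sim_panel_module):
        sets, hot = control_calls
        model = build_position_background(
            sets, sim_panel_module, alpha=0.99
        )
        probe = sim_panel_module.probes[0]
        assert SubKey(probe.chrom, probe.start + 10, probe.region_seq[10],
                      "A") not in model.positional

    def test_insufficient_controls_rejected(self, control_calls, sim_panel_module):
        sets, _ = control_calls
        with pytest.raises(InsufficientControlsError):
            build_position_background(sets[:1], sim_panel_module)

    def test_generic_class_count_bounded(self, control_calls, sim_panel_module):
        sets, _ = control_calls
        model = build_generic_background(sets, sim_panel_module, alpha=0.99)
        # 32 pyrimidine-centred contexts x 3 alts
        assert 0 < len(model.generic) <= 96
        for (context, alt), dist in model.generic.items():
            assert context[1] in "CT" and alt != context[1]

    def test_tsv_round_trip(self, control_calls, sim_panel_module, tmp_path):
        sets, hot = control_calls
        model = build_position_background(
            sets, sim_panel_module, alpha=0.999, outlier_drop=1
        )
        path = tmp_path / "model.tsv"
        model.to_tsv(path)
        back = BackgroundModel.from_tsv(path)
        assert back.kind == model.kind and back.alpha == model.alpha
        assert set(back.positional) == set(model.positional)
        for key, dist in model.positional.items():
            assert back.positional[key].high == pytest.approx(dist.high)
        assert set(back.generic) == set(model.generic)


class TestFilterVariants:
    def _model(self, sets, panel):
        return build_position_background(sets, panel, alpha=0.99, outlier_drop=0)

    def test_below_high_endpoint_not_significant(
        self, control_calls, sim_panel_module
    ):
        sets, hot = control_calls
        model = self._model(sets, sim_panel_module)
        probe = sim_panel_module.probes[0]
        ctx = probe.region_seq[39:42]
        calls = _calls([_call(hot.pos, hot.ref, hot.alt, 1.0e-3, ctx)])
        flagged = filter_variants(calls, model)
        assert not flagged["significant"].iloc[0]
        assert flagged["filter_route"].iloc[0] == ROUTE_POSITIONAL

    def test_above_high_endpoint_significant(self, control_calls, sim_panel_module):
        sets, hot = control_calls
        model = self._model(sets, sim_panel_module)
        probe = sim_panel_module.probes[0]
        ctx = probe.region_seq[39:42]
        calls = _calls([_call(hot.pos, hot.ref, hot.alt, 0.02, ctx)])
        assert filter_variants(calls, model)["significant"].iloc[0]

    def test_unseen_key_routed_to_generic_fallback(
        self, control_calls, sim_panel_module
    ):
        sets, hot = control_calls
        model = self._model(sets, sim_panel_module)
        probe = sim_panel_module.probes[0]
        ref = probe.region_seq[20]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        calls = _calls([
            _call(probe.start + 20, ref, alt, 5e-3, probe.region_seq[19:22])
        ])
        flagged = filter_variants(calls, model)
        assert flagged["filter_route"].iloc[0] == ROUTE_GENERIC

    def test_edge_position_never_significant(self, control_calls, sim_panel_module):
        sets, _ = control_calls
        model = self._model(sets, sim_panel_module)
        probe = sim_panel_module.probes[0]
        ref = probe.region_seq[0]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        calls = _calls([_call(probe.start, ref, alt, 0.4, ".")])
        flagged = filter_variants(calls, model)
        assert flagged["filter_route"].iloc[0] == ROUTE_EDGE
        assert not flagged["significant"].iloc[0]

    def test_sweep_monotone_over_fifteen_nines(
        self, control_calls, sim_panel_module, rng
    ):
        sets, hot = control_calls
        model = self._model(sets, sim_panel_module)
        probe = sim_panel_module.probes[0]
        rows = []
        for off in range(1, 120, 3):
            ref = probe.region_seq[off]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            vaf = float(10 ** rng.uniform(-4, -1.5))
            rows.append(_call(probe.start + off, ref, alt, vaf,
                              probe.region_seq[off - 1 : off + 2]))
        calls = _calls(rows)
        counts = significant_call_counts(calls, model, list(range(1, 16)))
        assert (counts.diff().dropna() <= 0).all()

    def test_extreme_alpha_can_reject_germline_het(self):
        # a tight nonzero background widens enormously at fifteen 9s
        dist = fit_background_distribution(
            np.array([0.01, 0.012, 0.009, 0.011]), alpha=0.9, outlier_drop=0
        )
        _, high_mild = ci_endpoints(dist, alpha_from_nines(1))
        _, high_extreme = ci_endpoints(dist, alpha_from_nines(15))
        assert high_mild < 0.5 < high_extreme


class TestSpectrum:
    def test_single_call_is_pure_class(self):
        calls = _calls([_call(100, "C", "T", 1e-3, "ACG")])
        spec = spectrum(calls)
        assert spec.by_class["C>T"] == 1.0
        assert spec.by_class.sum() == pytest.approx(1.0)

    def test_complement_collapse_merges_g_to_a(self):
        calls = _calls([
            _call(100, "C", "T", 1e-3, "ACG"),
            _call(200, "G", "A", 1e-3, "CGT"),
        ])
        spec = spectrum(calls)
        assert spec.by_class["C>T"] == 1.0

    def test_context_classes_canonical_and_normalised(self):
        calls = _calls([
            _call(100, "C", "T", 1e-3, "ACG"),
            _call(200, "G", "A", 1e-3, "CGT"),  # same class on other strand
            _call(300, "T", "G", 1e-3, "ATA"),
        ])
        spec = spectrum(calls)
        assert spec.by_context[("ACG", "T")] == pytest.approx(2 / 3)
        assert spec.by_context.sum() == pytest.approx(1.0)

    def test_ct_biased_errors_dominate_spectrum(self, sim_panel_module):
        # first-round PCR errors with the C>T artifact bias should give a
        # C>T-dominated spectrum, like real library damage
        from umivar.experiments import run_sample
        from umivar.simulate import SimConfig

        config = SimConfig(
            seed=77, captures_per_probe=3_000, reads_per_capture_mean=8,
            pcr_cycles=4, pcr_error_rate=0.0, seq_error_rate=0.0,
            first_round_errors=2_500, ct_bias=8.0,
        )
        run = run_sample(sim_panel_module, config, min_capture_support=1)
        calls = run.calls[run.calls["context"] != "."]
        # frequency-weighted: reflects error events, not distinct sites
        spec = spectrum(calls, weight="vaf")
        assert spec.by_class.idxmax() == "C>T"
        assert spec.by_class["C>T"] > 0.3
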