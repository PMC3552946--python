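import math

import pytest

from forestpi import (
    StudyRecord,
    build_forest_spec,
    pool_random,
    prediction_interval,
    rectangle_rationale_demo,
    render,
)
from forestpi.forest import ForestSpec
from conftest import data_to_frac, svg_group_xy, svg_x_extent


class TestBuildForestSpec:
    def test_rectangle_style_adds_separate_labeled_row(self, ratio_analysis):
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi, "rectangle")
        assert len(spec.study_rows) == 4
        assert len(spec.summary_rows) == 2
        diamond, rect = spec.summary_rows
        assert diamond.glyph == "diamond"
        assert rect.glyph == "rectangle"
        assert rect.label == "95% prediction interval"
        assert rect.lower == pytest.approx(math.exp(pi.lower))
        assert rect.upper == pytest.approx(math.exp(pi.upper))

    def test_style_none_has_single_diamond(self, ratio_analysis):
        studies, pool, _ = ratio_analysis
        spec = build_forest_spec(studies, pool, None, "none")
        assert [r.glyph for r in spec.summary_rows] == ["diamond"]

    def test_extended_diamond_merges_intervals_into_one_row(self, ratio_analysis):
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi, "extended_diamond")
        (row,) = spec.summary_rows
        assert row.glyph == "extended_diamond"
        assert row.lower == pytest.approx(math.exp(pi.lower))
        assert row.upper == pytest.approx(math.exp(pi.upper))
        assert row.ci_lower == pytest.approx(math.exp(pool.ci[0]))
        assert row.ci_upper == pytest.approx(math.exp(pool.ci[1]))

    def test_missing_pi_rejected(self, ratio_analysis):
        studies, pool, _ = ratio_analysis
        with pytest.raises(ValueError, match="requires a prediction interval"):
            build_forest_spec(studies, pool, None, "rectangle")

    def test_log_axis_for_ratio_measures(self, ratio_analysis):
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi)
        assert spec.axis.scale == "log"
        assert spec.axis.reference_line == 1.0
        assert all(v > 0 for v in spec.plotted_values())
        # ticks logarithmically placed from the 1-2-5 decade pattern
        assert all(
            any(abs(t / 10.0**e - m) < 1e-9 for e in range(-4, 5) for m in (1, 2, 5))
            for t in spec.axis.tick_values
        )

    def test_linear_axis_for_linear_measures(self, trio):
        pool = pool_random(trio)
        pi = prediction_interval(pool.pooled, pool.se_pooled, pool.tau2, 3)
        spec = build_forest_spec(trio, pool, pi)
        assert spec.axis.scale == "linear"
        assert spec.axis.reference_line == 0.0

    def test_annotations_report_tau_i2_q(self, ratio_analysis):
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi)
        note = spec.annotations
        assert f"{math.sqrt(pool.tau2):.2f}" in note
        assert f"{pool.i2:.0%}" in note
        assert f"df = {pool.q_df}" in note

    def test_json_round_trip(self, ratio_analysis):
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi)
        back = ForestSpec.from_json(spec.to_json())
        assert back == spec


class TestRender:
    def test_svg_deterministic(self, ratio_analysis, tmp_path):
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi)
        a = render(spec, tmp_path / "a.svg")
        b = render(spec, tmp_path / "b.svg")
        assert a.read_bytes() == b.read_bytes()

    @pytest.mark.parametrize("style", ["rectangle", "hollow_diamond", "extended_diamond"])
    def test_all_styles_render_both_formats(self, ratio_analysis, tmp_path, style):
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi, style)
        svg = render(spec, tmp_path / f"{style}.svg")
        png = render(spec, tmp_path / f"{style}.png")
        assert svg.stat().st_size > 0
        assert png.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"

    def test_rectangle_spans_pi_in_data_coordinates(self, ratio_analysis, tmp_path):
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi, "rectangle")
        svg = render(spec, tmp_path / "f.svg").read_text()
        ax0, ax1 = svg_x_extent(svg, "plot-area")
        r0, r1 = svg_x_extent(svg, "pi-rectangle")
        for px, value in ((r0, math.exp(pi.lower)), (r1, math.exp(pi.upper))):
            frac = (px - ax0) / (ax1 - ax0)
            expected = data_to_frac(value, spec.axis.limits, log=True)
            assert frac == pytest.approx(expected, abs=1e-3)

    def test_pi_glyph_class_differs_from_diamond(self, ratio_analysis, tmp_path):
        """The PI symbol is never the same symbol class as the CI diamond."""
        studies, pool, pi = ratio_analysis
        spec = build_forest_spec(studies, pool, pi, "rectangle")
        svg = render(spec, tmp_path / "f.svg").read_text()
        assert svg.count('id="pi-rectangle"') == 1
        rect_xs, rect_ys = svg_group_xy(svg, "pi-rectangle")
        dia_xs, dia_ys = svg_group_xy(svg, "summary-diamond")
        # rectangle: axis-aligned, 2 distinct y levels; diamond: 3 y levels
        assert len(set(round(y, 3) for y in rect_ys)) == 2
        assert len(set(round(y, 3) for y in dia_ys)) == 3

    def test_square_sides_scale_with_sqrt_weight(self, tmp_path):
        studies = [
            StudyRecord("a", 0.0, 0.1),
            StudyRecord("b", 0.1, 0.1 * math.sqrt(2)),
            StudyRecord("c", -0.1, 0.1 * math.sqrt(2)),
        ]
        pool = pool_random(studies, tau2_override=0.0)
        assert pool.weights == pytest.approx((0.5, 0.25, 0.25))
        pi = prediction_interval(pool.pooled, pool.se_pooled, 0.0, 3)
        spec = build_forest_spec(studies, pool, pi)
        svg = render(spec, tmp_path / "w.svg").read_text()
        sides = []
        for i in range(3):
            x0, x1 = svg_x_extent(svg, f"study-square-{i}")
            sides.append(x1 - x0)
        assert sides[0] / sides[1] == pytest.approx(math.sqrt(2), rel=1e-6)
        assert sides[1] == pytest.approx(sides[2], rel=1e-6)

    def test_log_axis_rejects_nonpositive_values_before_writing(self, trio, tmp_path):
        pool = pool_random(trio)
        pi = prediction_interval(pool.pooled, pool.se_pooled, pool.tau2, 3)
        spec = build_forest_spec(trio, pool, pi)  # linear: effects negative
        bad = ForestSpec(
            study_rows=spec.study_rows,
            summary_rows=spec.summary_rows,
            axis=spec.axis.__class__(
                scale="log",
                reference_line=1.0,
                tick_values=(1.0,),
                label="x",
                limits=(0.1, 10.0),
            ),
            pi_style=spec.pi_style,
        )
        out = tmp_path / "bad.svg"
        with pytest.raises(ValueError, match="positive"):
            render(bad, out)
        assert not out.exists()


class TestRectangleRationale:
    def test_inflation_one_is_identity_on_study_rows(self, ratio_studies):
        pool = pool_random(ratio_studies)
        pi = prediction_interval(
            pool.pooled, pool.se_pooled, pool.tau2, len(ratio_studies),
            scale_tag="log_ratio",
        )
        base = build_forest_spec(ratio_studies, pool, pi, "rectangle")
        demo = rectangle_rationale_demo(ratio_studies, 1.0)
        assert demo.study_rows == base.study_rows

    def test_large_inflation_shrinks_study_cis(self, ratio_studies):
        base = rectangle_rationale_demo(ratio_studies, 1.0)
        demo = rectangle_rationale_demo(ratio_studies, 1000.0)
        for b, d in zip(base.study_rows, demo.study_rows):
            bw = math.log(b.ci_upper) - math.log(b.ci_lower)
            dw = math.log(d.ci_upper) - math.log(d.ci_lower)
            assert dw < 0.01 * bw

    def test_pi_limit_is_between_study_spread(self, ratio_studies):
        """As SEs vanish the rectangle tends to
        center -/+ t * tau_hat * sqrt(1 + 1/k): the between-study spread
        plus the floor tau^2/k that the pooled-mean variance retains under
        random-effects weighting even for infinitely large studies."""
        from forestpi import tau2_dersimonian_laird
        from scipy import stats

        k = len(ratio_studies)
        demo = rectangle_rationale_demo(ratio_studies, 1e6)
        rect = demo.summary_rows[1]
        tau = math.sqrt(tau2_dersimonian_laird(ratio_studies))
        t = stats.t.ppf(0.975, k - 2)
        width_log = math.log(rect.upper) - math.log(rect.lower)
        assert width_log == pytest.approx(
            2 * t * tau * math.sqrt(1 + 1 / k), rel=1e-6
        )

    def test_inflation_below_one_rejected(self, ratio_studies):
        with pytest.raises(ValueError):
            rectangle_rationale_demo(ratio_studies, 0.5)
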