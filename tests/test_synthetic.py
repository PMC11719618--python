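"""Synthetic colony generator: exact ground truth and simulated samples."""

import math

import numpy as np
import pandas as pd
import pytest

from filametry import (
    ColonySpec,
    DoseDesign,
    DoseGroup,
    Filament,
    default_designs,
    render_colony,
    simulate_fmeasures,
    generate_image_dataset,
)
from filametry.synthetic import parse_design_file

from conftest import spoke_spec
from _oracles import rasterize_colony_bruteforce


class TestRenderColony:
    def test_disc_only_has_zero_f(self, disc_spec):
        _, truth = render_colony(disc_spec)
        assert truth.f_true == 0.0
        assert truth.a_outer_true == truth.a_inner_true

    def test_eight_spokes_matches_area_arithmetic(self):
        # 8 non-overlapping 50x10 spokes on r=100: added area ~ 8*500,
        # f ~ 8*500 / (pi*100^2) = 0.127 up to rasterization of the
        # curved attachment boundary.
        spec = spoke_spec(8, radius=100, length=50, width=10)
        _, truth = render_colony(spec)
        assert truth.a_inner_true == pytest.approx(math.pi * 100**2, rel=0.01)
        assert truth.f_true == pytest.approx(8 * 500 / (math.pi * 100**2), rel=0.08)

    def test_ground_truth_agrees_with_pointwise_oracle(self):
        # brute-force per-pixel point tests + border flood fill must agree
        # exactly with the generator's pixel counting
        spec = spoke_spec(4, radius=30, length=20, width=6, margin=10)
        _, truth = render_colony(spec)
        a_inner, a_outer = rasterize_colony_bruteforce(spec)
        assert truth.a_inner_true == a_inner
        assert truth.a_outer_true == a_outer

    def test_zero_length_filament_adds_nothing(self):
        spec = ColonySpec(
            image_width=300, image_height=300, inner_radius=80,
            filaments=(Filament(angle=0.3, length=0.0, width=5.0),),
        )
        _, truth = render_colony(spec)
        assert truth.f_true == 0.0

    def test_detached_filament_rejected(self):
        with pytest.raises(ValueError, match="detached"):
            ColonySpec(
                image_width=300, image_height=300, inner_radius=50,
                filaments=(Filament(angle=0.0, length=20, width=5, start_radius=60),),
            )

    @pytest.mark.parametrize(
        "kw",
        [
            {"inner_radius": 0},
            {"inner_radius": -5},
            {"foreground_level": 50, "background_level": 60},
            {"noise_sd": -1},
            {"filaments": (Filament(angle=0, length=10, width=0.5),)},
            {"filaments": (Filament(angle=0, length=10, width=90),)},
            {"filaments": (Filament(angle=0, length=-3, width=5),)},
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        base = dict(image_width=200, image_height=200, inner_radius=80)
        base.update(kw)
        with pytest.raises(ValueError):
            ColonySpec(**base)

    def test_noiseless_render_is_deterministic(self, disc_spec):
        img1, _ = render_colony(disc_spec)
        img2, _ = render_colony(disc_spec)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)

    def test_adding_filament_never_decreases_f(self):
        # monotonicity: each added non-overlapping spoke grows the union
        f_prev = -1.0
        for k in range(0, 7):
            spec = spoke_spec(max(k, 1), radius=60, length=30, width=6, margin=12)
            if k == 0:
                spec = ColonySpec(
                    image_width=spec.image_width, image_height=spec.image_height,
                    inner_radius=60,
                )
            _, truth = render_colony(spec)
            assert truth.f_true >= f_prev
            f_prev = truth.f_true

    def test_inverted_rendering_swaps_levels_only(self, disc_spec):
        _, truth_normal = render_colony(disc_spec)
        inv = ColonySpec(
            image_width=300, image_height=300, inner_radius=80, inverted=True
        )
        img, truth_inv = render_colony(inv)
        assert truth_inv == truth_normal
        # colony is now darker than agar
        assert img.pixels[150, 150, 0] < img.pixels[2, 2, 0]


class TestSimulateFMeasures:
    def test_zero_variance_group_is_constant(self):
        design = DoseDesign(groups=[DoseGroup(0.0, 5, 1.0, 0.0)])
        table = simulate_fmeasures(design)
        assert list(table["f"]) == [1.0] * 5

    @pytest.mark.parametrize("family", ["lognormal", "gamma", "truncated-normal"])
    def test_moment_recovery_within_two_percent(self, family):
        design = DoseDesign(
            groups=[DoseGroup(0.0, 10_000, 0.85, 0.6)], family=family, seed=11
        )
        f = simulate_fmeasures(design)["f"]
        assert f.min() >= 0
        assert f.mean() == pytest.approx(0.85, rel=0.02)
        assert f.std(ddof=1) == pytest.approx(0.6, rel=0.02)

    def test_reference_design_group_sizes_and_mean(self):
        # D. bruxellensis x tryptophol panel: the 100 uM group has n = 79
        # and a sample mean within 3 standard errors of 2.085 (sd 1.547)
        design = default_designs(seed=5)[("D. bruxellensis", "tryptophol")]
        table = simulate_fmeasures(design)
        grp = table[table["concentration_uM"] == 100.0]["f"]
        assert len(grp) == 79
        assert abs(grp.mean() - 2.085) < 3 * 1.547 / math.sqrt(79)

    def test_fixed_seed_reproduces_table(self):
        design = default_designs(seed=3)[("D. anomalous", "2-phenylethanol")]
        t1 = simulate_fmeasures(design)
        t2 = simulate_fmeasures(design)
        pd.testing.assert_frame_equal(t1, t2)

    def test_outlier_salting_marks_and_scales(self):
        design = DoseDesign(
            groups=[DoseGroup(0.0, 2000, 1.0, 0.1)],
            outlier_rate=0.05, outlier_scale=50.0, seed=2,
        )
        table = simulate_fmeasures(design)
        assert 0.02 < table["is_outlier"].mean() < 0.08
        assert table.loc[table["is_outlier"], "f"].min() > table.loc[~table["is_outlier"], "f"].max()

    def test_truncated_normal_infeasible_cv_names_group(self):
        design = DoseDesign(
            groups=[DoseGroup(50.0, 10, 1.0, 1.5)], family="truncated-normal",
            strain="s", compound="c",
        )
        with pytest.raises(ValueError, match="50"):
            simulate_fmeasures(design)

    @pytest.mark.parametrize(
        "groups",
        [
            [],
            [DoseGroup(0.0, 1, 1.0, 0.1)],
            [DoseGroup(0.0, 5, 1.0, 0.1), DoseGroup(0.0, 5, 2.0, 0.1)],
            [DoseGroup(-1.0, 5, 1.0, 0.1)],
            [DoseGroup(0.0, 5, 0.0, 0.1)],
        ],
    )
    def test_invalid_designs_rejected(self, groups):
        with pytest.raises(ValueError):
            DoseDesign(groups=groups).validate()

    def test_default_designs_cover_four_panels_at_five_doses(self):
        designs = default_designs()
        assert len(designs) == 4
        for d in designs.values():
            assert [g.concentration_uM for g in d.groups] == [0, 10, 50, 100, 200]


class TestDatasets:
    def test_image_dataset_roundtrip(self, tmp_path):
        specs = [spoke_spec(k, radius=40, length=20, width=6, margin=10, seed=k)
                 for k in (1, 4)]
        manifest, truths = generate_image_dataset(tmp_path, specs)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "ground_truth.csv").exists()
        for fname in manifest["file"]:
            assert (tmp_path / fname).exists()
        back = pd.read_csv(tmp_path / "ground_truth.csv")
        pd.testing.assert_frame_equal(back, truths)

    def test_design_file_roundtrip(self, tmp_path):
        cfg = tmp_path / "design.cfg"
        cfg.write_text(
            "# five-dose panel\n"
            "family = gamma\n"
            "strain = D. bruxellensis\n"
            "compound = 2-phenylethanol\n"
            "seed = 9\n"
            "group = 0 99 0.330 0.217\n"
            "group = 10 62 0.398 0.192\n"
        )
        design = parse_design_file(cfg)
        assert design.family == "gamma"
        assert len(design.groups) == 2
        assert design.groups[1].n == 62

    def test_design_file_bad_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("wibble = 3\n")
        with pytest.raises(ValueError, match="wibble"):
            parse_design_file(cfg)
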