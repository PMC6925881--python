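import dataclasses
import logging
import math

import numpy as np
import pytest

from spectrocycle.channels import builtin_channels
from spectrocycle.endmembers import FLUOROPHORES, build_endmember_matrix, default_endmembers
from spectrocycle.synth import (
    Artefacts,
    DatasetConfig,
    PackingError,
    PhaseEffectSpec,
    default_phase_effects,
    make_dataset,
    render_stack,
    sample_scene,
    sample_true_abundances,
)

EFFECTS = default_phase_effects()
SHAPE = (200, 200)


class TestSampleScene:
    def test_empty_plan_is_valid(self):
        plan = sample_scene({}, SHAPE, EFFECTS, seed=0)
        assert plan.cells == ()

    def test_determinism(self):
        counts = {("HeLa", "G1"): 5, ("PANC1", "M"): 3}
        p1 = sample_scene(counts, SHAPE, EFFECTS, seed=42)
        p2 = sample_scene(counts, SHAPE, EFFECTS, seed=42)
        assert p1 == p2
        p3 = sample_scene(counts, SHAPE, EFFECTS, seed=43)
        assert p1 != p3

    def test_cells_disjoint_and_in_bounds(self):
        counts = {("HeLa", ph): 25 for ph in ("G1", "S", "G2", "M")}
        plan = sample_scene(counts, (1024, 1024), EFFECTS, seed=7)
        assert len(plan.cells) == 100
        for cell in plan.cells:
            r, c = cell.centre
            a = max(cell.semi_axes)
            assert a <= r <= 1024 - a and a <= c <= 1024 - a
        for i, ci in enumerate(plan.cells):
            for cj in plan.cells[i + 1:]:
                d = math.dist(ci.centre, cj.centre)
                assert d >= max(ci.semi_axes) + max(cj.semi_axes)

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            sample_scene({("HeLa", "G1"): 50}, (40, 40), EFFECTS, seed=0)

    def test_phase_effect_spec_validation(self):
        with pytest.raises(ValueError):
            PhaseEffectSpec("HeLa", "G1", (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            PhaseEffectSpec("HeLa", "G1", (1.0, -1.0, 1.0, 1.0))


class TestRenderStack:
    def test_bit_identical_for_fixed_seed(self):
        plan = sample_scene({("HeLa", "G1"): 4}, SHAPE, EFFECTS, seed=1)
        cs = builtin_channels()
        s1, m1, t1 = render_stack(plan, cs, seed=5)
        s2, m2, t2 = render_stack(plan, cs, seed=5)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        np.testing.assert_array_equal(m1, m2)
        assert t1.drop(columns=[]).equals(t2)

    def test_empty_plan_background_zero(self):
        art = Artefacts(background_level=0.0, vignette_coeffs=(1.0,),
                        dead_pixel_rate=0.0, saturated_pixel_rate=1e-3)
        plan = sample_scene({}, (64, 64), EFFECTS, seed=0, artefacts=art)
        stack, mask, truth = render_stack(plan, builtin_channels(), seed=0)
        px = stack.pixels
        # Poisson of zero is zero everywhere except injected saturated pixels
        assert set(np.unique(px)) <= {0, 65535}
        assert mask.sum() == 0 and truth.empty

    def test_cell_mean_spectrum_follows_mixing_model(self):
        # law-of-large-numbers check at high photon count
        art = Artefacts(background_level=0.0, vignette_coeffs=(1.0,),
                        dead_pixel_rate=0.0, saturated_pixel_rate=0.0,
                        photon_scale=1e4)
        plan = sample_scene({("PANC1", "S"): 3}, SHAPE, EFFECTS, seed=3,
                            artefacts=art)
        cs = builtin_channels()
        m_phys = build_endmember_matrix(default_endmembers(), cs).physical()
        stack, mask, truth = render_stack(plan, cs, seed=9)
        for cell in plan.cells:
            measured = stack.pixels[mask == cell.cell_id].mean(axis=0)
            expected = 1e4 * (m_phys @ np.asarray(cell.abundance))
            rel = np.linalg.norm(measured - expected) / np.linalg.norm(expected)
            assert rel < 0.005

    def test_poisson_variance_matches_mean(self):
        art = Artefacts(background_level=40.0, vignette_coeffs=(1.0,),
                        dead_pixel_rate=0.0, saturated_pixel_rate=0.0)
        plan = sample_scene({}, (24, 24), EFFECTS, seed=0, artefacts=art)
        cs = builtin_channels()
        reps = np.stack([
            render_stack(plan, cs, seed=s)[0].pixels[:, :, 0].astype(float)
            for s in range(200)
        ])
        ratio = reps.var(axis=0).mean() / reps.mean(axis=0).mean()
        assert abs(ratio - 1.0) < 0.1

    def test_saturation_warning_logged(self, caplog):
        art = Artefacts(background_level=1e6, vignette_coeffs=(1.0,),
                        dead_pixel_rate=0.0, saturated_pixel_rate=0.0)
        plan = sample_scene({}, (32, 32), EFFECTS, seed=0, artefacts=art)
        with caplog.at_level(logging.WARNING, logger="spectrocycle.synth"):
            render_stack(plan, builtin_channels(), seed=0)
        assert any("saturates" in r.message for r in caplog.records)


class TestMakeDataset:
    def test_counts_and_truth_rows(self):
        cfg = DatasetConfig().small(2)
        ds = make_dataset(cfg, seed=0)
        assert len(ds.truth) == 24  # 3 lines x 4 phases x 2
        assert len(ds.stacks) == 12
        counts = ds.truth.groupby(["line", "phase"]).size()
        assert (counts == 2).all()

    def test_determinism_across_runs(self):
        cfg = DatasetConfig().small(2)
        d1 = make_dataset(cfg, seed=11)
        d2 = make_dataset(cfg, seed=11)
        for s1, s2 in zip(d1.stacks, d2.stacks):
            np.testing.assert_array_equal(s1.pixels, s2.pixels)
        assert d1.truth.equals(d2.truth)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(dataclasses.replace(DatasetConfig(), n_per_group=0))

    def test_between_line_separation_dominates_between_phase(self):
        # compare mean noiseless spectra: line-vs-line distance should exceed
        # 5x the within-line phase-vs-phase distance
        m_phys = build_endmember_matrix(
            default_endmembers(), builtin_channels()).physical()
        effects = default_phase_effects()
        spectra = {
            key: m_phys @ np.asarray(spec.abundance_mean)
            for key, spec in effects.items()
        }
        lines = ("HeLa", "MIA_PaCa_2", "PANC1")
        line_mean = {
            ln: np.mean([spectra[(ln, ph)] for ph in ("G1", "S", "G2", "M")],
                        axis=0)
            for ln in lines
        }
        between_line = np.mean([
            np.linalg.norm(line_mean[a] - line_mean[b])
            for i, a in enumerate(lines) for b in lines[i + 1:]
        ])
        within_phase = np.mean([
            np.linalg.norm(spectra[(ln, pa)] - spectra[(ln, pb)])
            for ln in lines
            for i, pa in enumerate(("G1", "S", "G2", "M"))
            for pb in ("G1", "S", "G2", "M")[i + 1:]
        ])
        assert between_line > 5 * within_phase


class TestTrueAbundances:
    def test_encoded_effect_directions(self):
        tab = sample_true_abundances(200, seed=31)
        med = tab.groupby(["line", "phase"]).median(numeric_only=True)
        for line in ("MIA_PaCa_2", "PANC1"):
            assert (med.loc[(line, "S"), "frac_NADPH_bound"]
                    > med.loc[(line, "G1"), "frac_NADPH_bound"])
        for line in ("HeLa", "PANC1"):
            assert (med.loc[(line, "M"), "frac_PPIX"]
                    > med.loc[(line, "G1"), "frac_PPIX"])
            assert (med.loc[(line, "G1"), "redox_ratio"]
                    > med.loc[(line, "M"), "redox_ratio"])
            assert (med.loc[(line, "G1"), "bound_free_ratio"]
                    > med.loc[(line, "M"), "bound_free_ratio"])

    def test_null_mode_removes_phase_effects(self):
        effects = default_phase_effects(null=True)
        for line in ("HeLa", "PANC1"):
            means = {ph: effects[(line, ph)].abundance_mean
                     for ph in ("G1", "S", "G2", "M")}
            assert len(set(means.values())) == 1

    def test_fractions_sum_to_one(self):
        tab = sample_true_abundances(10, seed=1)
        total = sum(tab[f"frac_{f}"] for f in FLUOROPHORES)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
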