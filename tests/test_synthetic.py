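"""Stokes–Einstein diffusion, mass-action equilibria and study generation."""

import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from coldcop import (
    Condition,
    KnownLigandSpec,
    LigandSpec,
    MixtureModel,
    NoiseModel,
    ProteinSpec,
    Scenario,
    d_free_from_mass,
    fit_decay,
    generate_decays,
    generate_study,
    lysozyme_like,
    observed_d,
    solve_equilibrium,
    tyrosinase_like,
)
from coldcop.synthetic import DEFAULT_SCHEME, compound_observed_d


def quadratic_f_bound(p_tot, l_tot, kd):
    """Closed-form single-site bound fraction (numerically stable root)."""
    s = p_tot + l_tot + kd
    pl = 2.0 * p_tot * l_tot / (s + math.sqrt(s * s - 4.0 * p_tot * l_tot))
    return pl / l_tot


def lsq_equilibrium_oracle(model):
    """Independent route: solve the full mass-action system in log space."""
    binders = [l for l in model.ligands if l.kd is not None]
    kd = np.array([l.kd for l in binders])
    alpha = np.array([l.alpha for l in binders])
    l_tot = np.array([l.concentration for l in binders])
    p_tot = model.protein.concentration
    k_tot = model.known.concentration if model.known else 0.0
    kk = model.known.kd_known if model.known else 1.0

    def residuals(logx):
        p, k = np.exp(logx[0]), np.exp(logx[1]) if model.known else 0.0
        lf = np.exp(logx[2:])
        pl = p * lf / kd
        plk = alpha * p * lf * k / (kd * kk)
        pk = p * k / kk if model.known else 0.0
        res = [(p + pl.sum() + plk.sum() + pk - p_tot) / p_tot]
        if model.known:
            res.append((k + pk + plk.sum() - k_tot) / k_tot)
        else:
            res.append(logx[1])  # pin unused variable
        res.extend((lf + pl + plk - l_tot) / l_tot)
        return res

    x0 = np.log(np.concatenate([[p_tot / 2, max(k_tot / 2, 1e-30)], l_tot / 2]))
    sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    p, k = np.exp(sol.x[0]), np.exp(sol.x[1])
    lf = np.exp(sol.x[2:])
    f = (p * lf / kd) * (1.0 + alpha * k / kk) / l_tot
    return {l.name: f[i] for i, l in enumerate(binders)}


class TestDFreeFromMass:
    def test_protein_reference_value(self):
        # 14.3 kDa at 298 K, eta = 8.9e-4 Pa s, rho = 1.35 g/cm^3
        d = d_free_from_mass(14300.0, density=1350.0)
        assert d == pytest.approx(1.52e-10, rel=2e-3)

    def test_radius_implied_by_d(self):
        from scipy.constants import Boltzmann

        d = d_free_from_mass(14300.0, density=1350.0)
        r = Boltzmann * 298.0 / (6 * math.pi * 8.9e-4 * d)
        assert r == pytest.approx(1.61e-9, rel=5e-3)

    def test_similar_masses_within_default_resolution(self):
        d1, d2 = d_free_from_mass(121.0), d_free_from_mass(150.0)
        assert abs(d1 / d2 - (150.0 / 121.0) ** (1 / 3)) < 1e-12
        assert abs(math.log10(d1) - math.log10(d2)) < 0.05

    def test_mass_times_8_halves_d(self):
        assert d_free_from_mass(800.0) == pytest.approx(
            d_free_from_mass(100.0) / 2.0, rel=1e-12
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            d_free_from_mass(0.0)


class TestSolveEquilibrium:
    def test_no_protein_all_free(self):
        m = MixtureModel(
            ligands=(LigandSpec("L", 100.0, 1e-3, kd=1e-4),),
        )
        state = solve_equilibrium(m)
        assert state.f_bound["L"] == 0.0
        assert state.l_free["L"] == 1e-3

    def test_single_site_matches_quadratic_closed_form(self):
        # the experimental regime: 4 uM protein, 1 mM ligand
        m = MixtureModel(
            ligands=(LigandSpec("L", 138.0, 1e-3, kd=2e-4),),
            protein=ProteinSpec("P", 120000.0, 4e-6),
        )
        state = solve_equilibrium(m)
        expected = quadratic_f_bound(4e-6, 1e-3, 2e-4)
        assert state.f_bound["L"] == pytest.approx(expected, rel=1e-10)

    def test_alpha_one_equals_no_known_ligand(self):
        # with alpha = 1 the two sites are thermodynamically independent,
        # so each ligand's bound fraction equals its value without the
        # known ligand present at all
        ligands = (
            LigandSpec("A", 100.0, 1e-3, kd=5e-5, alpha=1.0),
            LigandSpec("B", 120.0, 5e-4, kd=2e-4, alpha=1.0),
        )
        protein = ProteinSpec("P", 20000.0, 1e-4)
        with_known = solve_equilibrium(
            MixtureModel(
                ligands=ligands,
                protein=protein,
                known=KnownLigandSpec("K", 200.0, 2e-3, kd_known=1e-4),
            )
        )
        without = solve_equilibrium(MixtureModel(ligands=ligands, protein=protein))
        for name in ("A", "B"):
            assert with_known.f_bound[name] == pytest.approx(
                without.f_bound[name], rel=1e-9
            )

    def test_matches_independent_least_squares_oracle(self):
        m = MixtureModel(
            ligands=(
                LigandSpec("A", 100.0, 1e-3, kd=5e-5, alpha=0.0),
                LigandSpec("B", 120.0, 5e-4, kd=2e-4, alpha=8.0),
            ),
            protein=ProteinSpec("P", 20000.0, 1e-4),
            known=KnownLigandSpec("K", 200.0, 2e-3, kd_known=1e-4),
        )
        got = solve_equilibrium(m).f_bound
        oracle = lsq_equilibrium_oracle(m)
        for name, f in oracle.items():
            assert got[name] == pytest.approx(f, rel=1e-7)

    @pytest.mark.parametrize("seed", range(1, 31))
    def test_conservation_on_random_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        ligands = tuple(
            LigandSpec(
                f"L{i}",
                mass=rng.uniform(60, 400),
                concentration=10 ** rng.uniform(-5, -2),
                kd=None if rng.random() < 0.3 else 10 ** rng.uniform(-6, -2),
                alpha=float(rng.uniform(0, 30)),
            )
            for i in range(rng.integers(1, 4))
        )
        ligands = tuple(
            l if l.kd is not None else LigandSpec(l.name, l.mass, l.concentration)
            for l in ligands
        )
        m = MixtureModel(
            ligands=ligands,
            protein=ProteinSpec("P", 20000.0, 10 ** rng.uniform(-6, -3)),
            known=KnownLigandSpec(
                "K", 200.0, 10 ** rng.uniform(-4, -2), kd_known=10 ** rng.uniform(-6, -3)
            ),
        )
        state = solve_equilibrium(m)
        assert max(state.residuals.values()) <= 1e-10
        assert all(0.0 <= f <= 1.0 for f in state.f_bound.values())

    def test_competitive_monotone_decreasing_in_known_concentration(self):
        f_prev = None
        for k_conc in np.logspace(-5, -2, 8):
            m = MixtureModel(
                ligands=(LigandSpec("probe", 138.0, 5e-4, kd=1e-5, alpha=0.0),),
                protein=ProteinSpec("P", 120000.0, 1e-4),
                known=KnownLigandSpec("K", 164.0, float(k_conc), kd_known=2e-5),
            )
            f = solve_equilibrium(m).f_bound["probe"]
            if f_prev is not None:
                assert f < f_prev
            f_prev = f

    def test_cooperative_monotone_increasing_in_known_concentration(self):
        f_prev = None
        for k_conc in np.logspace(-5, -2, 8):
            m = MixtureModel(
                ligands=(LigandSpec("probe", 121.0, 1e-3, kd=2e-3, alpha=20.0),),
                protein=ProteinSpec("P", 14300.0, 1e-3),
                known=KnownLigandSpec("K", 221.0, float(k_conc), kd_known=1e-4),
            )
            f = solve_equilibrium(m).f_bound["probe"]
            if f_prev is not None:
                assert f > f_prev
            f_prev = f

    def test_competitive_limit_probe_displaced(self):
        # alpha = 0, known ligand concentration -> large: probe f_bound -> 0
        m = MixtureModel(
            ligands=(LigandSpec("probe", 138.0, 5e-4, kd=1e-5, alpha=0.0),),
            protein=ProteinSpec("P", 120000.0, 1e-4),
            known=KnownLigandSpec("K", 164.0, 1.0, kd_known=2e-5),
        )
        assert solve_equilibrium(m).f_bound["probe"] < 1e-3

    def test_f_bound_monotone_in_alpha_and_protein(self):
        def f_at(alpha, p_conc):
            m = MixtureModel(
                ligands=(LigandSpec("L", 121.0, 1e-3, kd=2e-3, alpha=alpha),),
                protein=ProteinSpec("P", 14300.0, p_conc),
                known=KnownLigandSpec("K", 221.0, 2e-3, kd_known=1e-4),
            )
            return solve_equilibrium(m).f_bound["L"]

        fs = [f_at(a, 1e-3) for a in (0.0, 1.0, 5.0, 20.0)]
        assert all(a < b for a, b in zip(fs, fs[1:]))
        fs = [f_at(5.0, p) for p in (1e-5, 1e-4, 1e-3)]
        assert all(a < b for a, b in zip(fs, fs[1:]))


class TestObservedD:
    def test_endpoints(self):
        assert observed_d(0.0, 6e-10, 1e-10) == 6e-10
        assert observed_d(1.0, 6e-10, 1e-10) == 1e-10

    def test_midpoint(self):
        assert observed_d(0.5, 6e-10, 1e-10) == pytest.approx(3.5e-10)

    def test_always_between_bounds(self):
        for f in np.linspace(0, 1, 11):
            d = observed_d(float(f), 6e-10, 1e-10)
            assert 1e-10 <= d <= 6e-10

    def test_out_of_range_f_bound_rejected(self):
        with pytest.raises(ValueError, match="f_bound"):
            observed_d(1.2, 6e-10, 1e-10)


class TestGenerateDecays:
    def _model(self):
        return MixtureModel(
            ligands=(
                LigandSpec("L", 138.0, 5e-4, kd=1e-5, shifts=((7.0, 1.0), (7.4, 0.5))),
            ),
            protein=ProteinSpec("P", 120000.0, 2e-4),
        )

    def test_noiseless_round_trip_through_fit(self):
        model = self._model()
        d_expected = compound_observed_d(model)["L"]
        series = generate_decays(model, DEFAULT_SCHEME, NoiseModel(sigma=0.0))
        for s in series:
            peak = fit_decay(s, DEFAULT_SCHEME)
            assert peak.d == pytest.approx(d_expected, rel=1e-10)

    def test_same_seed_bit_identical(self):
        model = self._model()
        a = generate_decays(model, DEFAULT_SCHEME, NoiseModel(sigma=0.02, seed=5))
        b = generate_decays(model, DEFAULT_SCHEME, NoiseModel(sigma=0.02, seed=5))
        assert a == b

    def test_different_seeds_same_underlying_d(self):
        model = self._model()
        d_true = compound_observed_d(model)["L"]
        within = 0
        total = 0
        for seed in range(1, 21):
            for s in generate_decays(
                model, DEFAULT_SCHEME, NoiseModel(sigma=0.02, seed=seed)
            ):
                peak = fit_decay(s, DEFAULT_SCHEME)
                total += 1
                within += abs(peak.d - d_true) <= 2 * peak.sigma_d
        assert within / total >= 0.9

    def test_relative_intensity_scales_amplitudes(self):
        # both resonances of the compound decay at the same D, so their
        # intensity ratio is the relative-intensity ratio at every gradient
        series = generate_decays(
            self._model(), DEFAULT_SCHEME, NoiseModel(sigma=0.0), i0=1e4
        )
        ratio = np.array(series[1].intensities) / np.array(series[0].intensities)
        assert ratio == pytest.approx(np.full(len(ratio), 0.5), rel=1e-12)
        # extrapolated zero-gradient amplitude equals i0 * relative intensity
        assert fit_decay(series[0], DEFAULT_SCHEME).i0 == pytest.approx(1e4, rel=1e-9)


class TestGenerateStudy:
    def test_competitive_fixture_directions(self):
        study = generate_study(tyrosinase_like(), seed=7, noise_sigma=0.0)
        t = study.truth.set_index("compound")
        lp, lpk = "D_obs_ligand_protein", "D_obs_ligand_protein_known"
        assert t.loc["salicylate_probe", lp] < t.loc["salicylate_probe", lpk]
        for name in ("tris_like", "tartrate_like"):
            assert t.loc[name, lp] == pytest.approx(t.loc[name, lpk], rel=1e-12)

    def test_cooperative_fixture_directions(self):
        study = generate_study(lysozyme_like(), seed=7, noise_sigma=0.0)
        t = study.truth.set_index("compound")
        lp, lpk = "D_obs_ligand_protein", "D_obs_ligand_protein_known"
        for name in ("tris_probe", "imidazole_probe"):
            assert t.loc[name, lpk] < t.loc[name, lp]

    def test_zero_protein_all_conditions_identical(self):
        scn = tyrosinase_like(protein_concentration=0.0)
        study = generate_study(scn, seed=3, noise_sigma=0.0)
        t = study.truth
        for c1, c2 in (
            ("D_obs_ligand_only", "D_obs_ligand_protein"),
            ("D_obs_ligand_protein", "D_obs_ligand_protein_known"),
        ):
            ligand_rows = t[t.role != "known_ligand"]
            assert np.allclose(ligand_rows[c1], ligand_rows[c2])

    def test_study_deterministic_for_fixed_seed(self):
        a = generate_study(lysozyme_like(), seed=11)
        b = generate_study(lysozyme_like(), seed=11)
        for cond in Condition:
            assert a.decays[cond] == b.decays[cond]

    def test_inconsistent_scenario_rejected(self):
        with pytest.raises(ValueError, match="requires a kd"):
            Scenario(
                name="bad",
                ligands=(LigandSpec("x", 100.0, 1e-3),),
                protein=ProteinSpec("P", 14300.0, 1e-3),
                known=KnownLigandSpec("K", 200.0, 1e-3, kd_known=1e-4),
                roles=(("x", "competitive_probe"),),
            )
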