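"""End-to-end validation benchmarks run against phantom ground truth.

Each function regenerates its inputs from a seed, runs the relevant slice
of the pipeline, and returns the measured quantities. They back both the
validation test suite and the reproduction script, so the numbers reported
there are always recomputed, never cached.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .group_stats import auc_rank, compare_groups
from .image_io import ANALYSIS_REGIONS, binarize_segmentation
from .persi import build_histogram, fit_bimodal, fwhm_from_sigma, select_reference_voxels
from .phantom import PhantomSpec, build_geometry, generate_cohort, generate_subject
from .quantify import METHOD_CEREBELLUM, METHOD_PERSI, QuantConfig, compute_suvr_table, quantify_subject


def _hist_from_samples(samples: np.ndarray, n_bins: int = 128):
    from .image_io import BinaryMask, Volume3D

    n = len(samples)
    side = int(np.ceil(n ** (1 / 3)))
    data = np.zeros(side**3)
    data[:n] = samples
    mask = np.zeros(side**3, dtype=bool)
    mask[:n] = True
    return build_histogram(
        Volume3D(data.reshape(side, side, side), np.diag([2.0, 2.0, 2.0, 1.0])),
        BinaryMask(mask.reshape(side, side, side)),
        n_bins,
    )


def bimodal_recovery(seed: int, n_hist: int = 20, n_draws: int = 50_000) -> dict:
    """Fit recovery on seeded mixture histograms (component separation >= 3 sigma)
    and fallback behavior on matched unimodal histograms."""
    rng = np.random.default_rng(seed)
    mu_errs, sigma_errs = [], []
    fallbacks = 0
    for _ in range(n_hist):
        mu_lo = rng.uniform(0.8, 1.2)
        sd_lo = rng.uniform(0.08, 0.12)
        sd_hi = rng.uniform(0.10, 0.20)
        sep = rng.uniform(3.0, 6.0) * max(sd_lo, sd_hi)
        w_hi = rng.uniform(0.2, 0.4)
        n_hi = int(round(w_hi * n_draws))
        samples = np.concatenate(
            [
                rng.normal(mu_lo, sd_lo, n_draws - n_hi),
                rng.normal(mu_lo + sep, sd_hi, n_hi),
            ]
        )
        fit = fit_bimodal(_hist_from_samples(samples))
        mu_errs.append(abs(fit.mu_low / mu_lo - 1))
        sigma_errs.append(abs(fit.sigma_low / sd_lo - 1))

        uni = rng.normal(mu_lo, sd_lo, n_draws)
        fallbacks += fit_bimodal(_hist_from_samples(uni)).unimodal_fallback
    return {
        "median_mu_low_rel_err": float(np.median(mu_errs)),
        "median_sigma_low_rel_err": float(np.median(sigma_errs)),
        "unimodal_fallback_count": int(fallbacks),
        "n_hist": n_hist,
    }


def reference_purity(seed: int) -> dict:
    """Contamination fraction among retained reference voxels vs the analytic
    overlap of the true mixture inside the fitted FWHM window."""
    spec = PhantomSpec()
    pet, _, wm, _, truth = generate_subject(spec, "AD", seed)
    mask = binarize_segmentation(wm)
    fit = fit_bimodal(build_histogram(pet, mask))
    ref = select_reference_voxels(pet, mask, fit)
    observed = float((ref.mask.data & truth.contamination_labels).sum() / ref.n_voxels)

    half = 0.5 * fwhm_from_sigma(fit.sigma_low)
    a, b = fit.mu_low - half, fit.mu_low + half
    s = truth.global_scale
    f = truth.contamination_fraction
    m0, s0 = spec.wm_mean * s, spec.wm_sd * s
    mc = spec.wm_mean * (1 + spec.contamination_delta) * s
    sc = spec.contamination_sd * s
    p_clean = (1 - f) * (norm.cdf((b - m0) / s0) - norm.cdf((a - m0) / s0))
    p_cont = f * (norm.cdf((b - mc) / sc) - norm.cdf((a - mc) / sc))
    expected = float(p_cont / (p_cont + p_clean))
    mc_se = float(np.sqrt(expected * (1 - expected) / ref.n_voxels))
    return {
        "observed_contam_fraction": observed,
        "expected_contam_fraction": expected,
        "mc_se": mc_se,
        "n_retained": ref.n_voxels,
    }


def suvr_recovery(seed: int) -> dict:
    """Noiseless-phantom SUVR error against the programmed regional ratios."""
    spec = PhantomSpec.noiseless()
    from .phantom import build_atlas

    geom = build_geometry(spec)
    atlas = build_atlas(spec, geom)
    pet, _, wm, _, truth = generate_subject(spec, "AD", seed, geometry=geom)
    exact, _, _ = quantify_subject(pet, wm, atlas, QuantConfig(smooth=False))
    smoothed, _, _ = quantify_subject(pet, wm, atlas, QuantConfig(smooth=True))
    abs_errs = [
        abs(exact[m][r] - truth.regional_ratios[r])
        for m in (METHOD_PERSI, METHOD_CEREBELLUM)
        for r in ANALYSIS_REGIONS
    ]
    rel_errs = [
        abs(smoothed[m][r] / truth.regional_ratios[r] - 1)
        for m in (METHOD_PERSI, METHOD_CEREBELLUM)
        for r in ANALYSIS_REGIONS
    ]
    return {
        "max_abs_err_unsmoothed": float(max(abs_errs)),
        "max_rel_err_smoothed": float(max(rel_errs)),
        "n_suvrs": len(abs_errs),
    }


def scale_invariance(seed: int, factor: float = 3.7) -> dict:
    """Largest SUVR change under global intensity rescaling of the PET."""
    spec = PhantomSpec()
    from .phantom import build_atlas

    geom = build_geometry(spec)
    atlas = build_atlas(spec, geom)
    diffs = []
    for group in ("HC", "AD"):
        pet, _, wm, _, _ = generate_subject(spec, group, seed, geometry=geom)
        s1, _, _ = quantify_subject(pet, wm, atlas)
        s2, _, _ = quantify_subject(pet.with_data(pet.data * factor), wm, atlas)
        diffs += [abs(s1[m][r] - s2[m][r]) for m in s1 for r in s1[m]]
    return {"max_abs_suvr_change": float(max(diffs)), "n_suvrs": len(diffs)}


def auc_oracle(seed: int, n_instances: int = 100) -> dict:
    """Rank AUC vs brute-force pairwise counting, plus designed-effect recovery
    on a 50/50 phantom cohort built for temporal-lobe d* = 1.5."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_instances):
        na, nb = rng.integers(2, 20, size=2)
        a = np.round(rng.normal(0, 1, na), 1)  # rounding forces ties
        b = np.round(rng.normal(0.3, 1, nb), 1)
        wins = sum((y > x) + 0.5 * (y == x) for x in a for y in b)
        max_diff = max(max_diff, abs(auc_rank(a, b) - wins / (na * nb)))

    d_star = 1.5
    hc = {r: 1.0 for r in ANALYSIS_REGIONS}
    ad = dict(hc)
    ad["temporal_lobe"] = 1.0 + d_star * 0.1
    spec = PhantomSpec(uptake_ratios={"HC": hc, "MCI": hc, "AD": ad})
    with tempfile.TemporaryDirectory() as tmp:
        manifest, atlas, _ = generate_cohort(
            spec, {"HC": 50, "AD": 50}, master_seed=seed, out_dir=tmp
        )
        table = compute_suvr_table(manifest, atlas)
    comps = {(c.region, c.method): c for c in compare_groups(table, ("HC", "AD"))}
    comp = comps[("temporal_lobe", METHOD_PERSI)]
    target = float(norm.cdf(d_star / np.sqrt(2)))
    # Hanley-McNeil standard error of the empirical AUC
    q1 = target / (2 - target)
    q2 = 2 * target**2 / (1 + target)
    var = (
        target * (1 - target) + 49 * (q1 - target**2) + 49 * (q2 - target**2)
    ) / 2500
    return {
        "max_auc_bruteforce_diff": float(max_diff),
        "n_instances": n_instances,
        "designed_effect_auc": float(comp.auc),
        "designed_effect_d": float(comp.cohens_d),
        "binormal_target_auc": target,
        "auc_se": float(np.sqrt(var)),
    }


def persi_vs_cerebellum(seed: int, n_per_group: dict | None = None) -> dict:
    """Default spill-in cohort: per-region wins of PERSI-WM over the
    whole-cerebellum arm (HC vs AD), in both d and AUC."""
    spec = PhantomSpec()
    with tempfile.TemporaryDirectory() as tmp:
        manifest, atlas, _ = generate_cohort(spec, n_per_group, master_seed=seed, out_dir=tmp)
        table = compute_suvr_table(manifest, atlas)
    comps = {(c.region, c.method): c for c in compare_groups(table, ("HC", "AD"))}
    wins_d = wins_auc = 0
    per_region = {}
    for r in ANALYSIS_REGIONS:
        p = comps[(r, METHOD_PERSI)]
        c = comps[(r, METHOD_CEREBELLUM)]
        wins_d += p.cohens_d >= c.cohens_d
        wins_auc += p.auc >= c.auc
        per_region[r] = {
            "persi_d": p.cohens_d,
            "cereb_d": c.cohens_d,
            "persi_auc": p.auc,
            "cereb_auc": c.auc,
        }
    return {
        "regions_persi_d_ge_cereb": int(wins_d),
        "regions_persi_auc_ge_cereb": int(wins_auc),
        "n_regions": len(ANALYSIS_REGIONS),
        "per_region": per_region,
        "n_subjects": len(manifest),
    }


def cli_determinism(seed: int) -> dict:
    """Two identical end-to-end CLI runs must produce byte-identical CSVs."""
    from click.testing import CliRunner

    from .cli import main

    runner = CliRunner()
    csvs = ("suvr_long.csv", "group_summary.csv", "comparisons.csv")
    with tempfile.TemporaryDirectory() as tmp:
        outs = []
        for name in ("run1", "run2"):
            out = Path(tmp) / name
            res = runner.invoke(
                main,
                [
                    "all", "--out", str(out), "--seed", str(seed),
                    "--n-hc", "4", "--n-mci", "0", "--n-ad", "4",
                    "--pairs", "HC:AD",
                ],
                catch_exceptions=False,
            )
            if res.exit_code != 0:
                raise RuntimeError(f"CLI run failed: {res.output}")
            outs.append(out)
        identical = all(
            filecmp.cmp(outs[0] / c, outs[1] / c, shallow=False) for c in csvs
        )
    return {"identical": bool(identical), "n_files": len(csvs)}
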