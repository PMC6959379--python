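"""Reproducible benchmark studies of the estimators.

Each study generates its own synthetic inputs with the package's
generators, runs the corresponding estimator, and summarizes the error —
a round trip against known ground truth.  They are used by the test
suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import community, nexafs, synthetic


def nexafs_recovery_study(n_spectra: int = 50, noise_sd: float = 0.01,
                          edge: str = "C1s", seed: int = 0) -> dict:
    """Fit seeded synthetic spectra and summarize pi*-abundance recovery.

    Compositions are drawn from a flat-ish Dirichlet over the edge's
    canonical components; noise is i.i.d. Gaussian on intensity
    (``noise_sd`` is in edge-jump units, so 0.01 is 1% of the jump).

    Returns per-component RMSE, the maximum per-component RMSE, the
    overall RMSE, the maximum absolute error and the convergence count.
    """
    labels = list(nexafs.edge_info(edge)["pi"])
    rng = np.random.default_rng(seed)
    errors = np.zeros((n_spectra, len(labels)))
    converged = 0
    for i in range(n_spectra):
        fracs = rng.dirichlet(np.full(len(labels), 2.0))
        truth = synthetic.NexafsGroundTruth(
            edge, dict(zip(labels, fracs)), noise_sd=noise_sd,
            seed=int(rng.integers(2 ** 31)))
        s, _ = synthetic.gen_nexafs_spectrum(truth)
        fit = nexafs.fit_spectrum(nexafs.normalize_edge_jump(s), seed=seed)
        converged += bool(fit.converged)
        errors[i] = [fit.pi_abundances[l] - truth.true_relative_abundances[l]
                     for l in labels]
    rmse_per_component = np.sqrt((errors ** 2).mean(axis=0))
    return {
        "labels": labels,
        "rmse_per_component": dict(zip(labels, rmse_per_component)),
        "max_component_rmse": float(rmse_per_component.max()),
        "overall_rmse": float(np.sqrt((errors ** 2).mean())),
        "max_abs_error": float(np.abs(errors).max()),
        "n_converged": converged,
        "n_spectra": n_spectra,
    }


def permanova_type1_study(n_sims: int = 500, n_perm: int = 999,
                          n_samples: int = 8, n_otus: int = 30,
                          depth: int = 1000, alpha: float = 0.05,
                          seed: int = 0) -> dict:
    """Type-I error of PERMANOVA on null communities.

    Every simulated dataset draws all samples from one shared
    composition (no group effect), splits them into two equal arbitrary
    groups, and tests at ``alpha``.  Under a correct test the rejection
    rate matches ``alpha``.
    """
    rng = np.random.default_rng(seed)
    labels = ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2)
    rejections = 0
    for _ in range(n_sims):
        comp = rng.dirichlet(np.full(n_otus, 1.0))
        counts = rng.multinomial(depth, comp, size=n_samples).T  # otus x samples
        d = community.bray_curtis(pd.DataFrame(counts))
        res = community.permanova(d, labels, n_perm=n_perm,
                                  seed=int(rng.integers(2 ** 31)))
        rejections += res.p_value <= alpha
    return {
        "rejection_rate": rejections / n_sims,
        "n_sims": n_sims,
        "n_permutations": n_perm,
        "alpha": alpha,
    }


def rarefaction_study(n_seeds: int = 200, true_prop: float = 0.25,
                      total: int = 400, depth: int = 100,
                      seed: int = 0) -> dict:
    """Conservation and unbiasedness of rarefaction.

    One sample with a focal OTU at ``true_prop`` is rarefied under
    ``n_seeds`` different seeds; subsampling without replacement is
    hypergeometric, so the mean rarefied proportion must match the true
    proportion and every column sum must equal the depth.
    """
    focal = int(round(true_prop * total))
    rest = total - focal
    counts = pd.DataFrame({"s": [focal, rest // 2, rest - rest // 2]},
                          index=["focal", "x", "y"])
    table = community.OtuTable(counts)
    rng = np.random.default_rng(seed)
    props = []
    sums_ok = True
    for _ in range(n_seeds):
        out = community.rarefy(table, depth=depth,
                               seed=int(rng.integers(2 ** 31)))
        sums_ok &= bool((out.counts.sum(axis=0) == depth).all())
        props.append(out.counts.loc["focal", "s"] / depth)
    return {
        "mean_proportion": float(np.mean(props)),
        "true_proportion": true_prop,
        "all_sums_equal_depth": sums_ok,
        "n_seeds": n_seeds,
        "depth": depth,
    }
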