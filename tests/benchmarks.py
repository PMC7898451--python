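"""End-to-end benchmark helpers shared by the acceptance checks.

Each helper generates data with the synthetic module, runs the full
pipeline, and measures one headline quantity.  Benchmarks use 1000 cells
from 5 cell types (the generator's documented scaled-down benchmark shape)
with the generator's default strong-separation parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, kstest

from cellsorter.containers import ExpressionMatrix, MarkerSpec, ProblemInstance
from cellsorter.pipeline import misclassification_rate, run_pipeline
from cellsorter.preprocess import build_design, log_normalize
from cellsorter.simulate import SimConfig, simulate
from cellsorter.step1 import run_step1
from cellsorter.step2 import UNKNOWN_LABEL, compute_beta

BENCH_N_CELLS = 1000
BENCH_N_TYPES = 5


def scenario_run(scenario, n_removed, seed, w0=2.0, n_restarts=10):
    config = SimConfig(
        n_cells=BENCH_N_CELLS,
        n_types=BENCH_N_TYPES,
        scenario=scenario,
        n_removed=n_removed,
        seed=seed,
    )
    sim = simulate(config)
    expr = log_normalize(sim.counts)
    instance = build_design(expr, sim.marker_table, hvg=None, w0=w0)
    result = run_pipeline(instance, n_restarts=n_restarts,
                          base_seed=1000 + seed)
    return sim, result


def scenario1_error(seed, w0=2.0):
    sim, result = scenario_run(1, 0, seed, w0=w0)
    return misclassification_rate(result.labels, sim.truth_labels)


def scenario2_absent_fraction(seed):
    sim, result = scenario_run(2, 1, seed)
    absent = set(sim.scenario_record["removed_types"])
    return float(np.mean([label in absent for label in result.labels]))


def scenario3_recall_and_known_error(seed):
    sim, result = scenario_run(3, 1, seed)
    truth = np.asarray(sim.truth_labels)
    pred = np.asarray(result.labels)
    alien = truth == UNKNOWN_LABEL
    recall = float((pred[alien] == UNKNOWN_LABEL).mean())
    known_err = float((pred[~alien] != truth[~alien]).mean())
    return recall, known_err


def step1_oracle_match(n_instances, rng_seed, n_restarts=20):
    """Fraction of tiny instances where multi-restart hits the enumerated
    global optimum of the clustering objective (cost gap < 1e-6)."""
    from oracles import global_optimum, random_tiny_instance

    rng = np.random.default_rng(rng_seed)
    hits = 0
    for _ in range(n_instances):
        instance, _ = random_tiny_instance(rng, N=8, K=2, g=2, h=3)
        opt_cost, _ = global_optimum(instance)
        best = min(
            run_step1(instance, seed=s).cost for s in range(n_restarts)
        )
        assert best > opt_cost - 1e-6, "solver undercut the exhaustive oracle"
        hits += best < opt_cost + 1e-6
    return hits


def beta_null_ks_pvalue(seed, h=10, n_decided=2000, n_undecided=1000):
    """KS uniformity p-value for beta under the null.

    Decided cells are Gaussian per gene; undecided cells are drawn from the
    per-gene Gaussians FITTED to the decided set, then screened with the
    package's chi-square statistic.
    """
    rng = np.random.default_rng(seed)
    d_vals = rng.normal(5.0, 1.0, (h, n_decided))
    nu_hat = d_vals.mean(axis=1)
    sd_hat = d_vals.std(axis=1, ddof=1)
    u_vals = rng.normal(
        nu_hat[:, None], sd_hat[:, None], (h, n_undecided)
    )
    x = np.hstack([d_vals, u_vals])
    x = np.vstack([np.zeros((1, x.shape[1])), x]) - min(x.min(), 0.0)
    expr = ExpressionMatrix(
        x, ["m0"] + [f"n{i}" for i in range(h)],
        [f"c{j}" for j in range(x.shape[1])], is_lognorm=True,
    )
    spec = MarkerSpec(["T0"], ["m0"], np.array([[True]]), np.ones((1, 1)))
    instance = ProblemInstance(expr=expr, spec=spec, g=1, h=h)
    d_k = np.arange(n_decided)
    betas = np.array([
        compute_beta(instance, d_k, n_decided + j) for j in range(n_undecided)
    ])
    return float(kstest(betas, "uniform").pvalue)
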