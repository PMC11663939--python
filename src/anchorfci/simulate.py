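"""Random partially-ordered MAGs, mixed-data simulation, and the
RFCI-vs-anchorFCI benchmark.

The generator emulates a genotype/phenotype design: a handful of 3-level
multinomial anchors (G1, G2, ...) precede a block of continuous interest
variables (A, B, ...) in the causal order.  Interest variables follow a
linear Gaussian structural equation model with sign-balanced random
coefficients; latent confounders may connect interest pairs, and the
ground-truth MAG over the observed nodes is obtained by latent projection.

Structure recovery is scored by the Structural Hamming Distance over edges
among the interest variables only, reported as the *SHD-difference*:
SHD(inferred PAG, true MAG) minus SHD(true MEC PAG, true MAG) — zero means
"as informative as the best PAG obtainable without background knowledge",
negative means strictly more informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .citest import CONTINUOUS, MULTINOMIAL, MixedCITester
from .engine import DiscoveryConfig, run_discovery
from .estimators import AnchorFCI, ConservativeRFCI, VariableRoles
from .graph import ARROWHEAD, MAG, PAG, TAIL, MarkedGraph, latent_project, shd
from .citest import oracle_ci

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-design parameters of the simulation benchmark.

    Defaults mirror the benchmark design: 8-node systems with anchors
    {G1,G2,G3} preceding interest variables {A..E}, 3-level multinomial
    anchors, linear-Gaussian interest variables with latent confounding,
    evaluated on 50 MAGs x 30 datasets at N in {500, 1000, 5000, 10000}.
    """

    n_anchors: int = 3
    n_interest: int = 5
    interest_edge_prob: float = 0.4
    latent_confounder_prob: float = 0.5
    anchor_children: int = 1
    coef_low: float = 0.3
    coef_high: float = 1.0
    anchor_level_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    noise_scale: float = 1.0
    sample_sizes: tuple[int, ...] = (500, 1000, 5000, 10000)
    n_mags: int = 50
    n_datasets: int = 30

    def __post_init__(self):
        if not np.isclose(sum(self.anchor_level_probs), 1.0):
            raise ValueError("anchor level probabilities must sum to 1")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")

    @property
    def anchor_names(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_anchors)]

    @property
    def interest_names(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_interest)]

    def roles(self) -> VariableRoles:
        return VariableRoles(
            interest=tuple(self.interest_names), anchors=tuple(self.anchor_names)
        )

    def types(self) -> dict[str, str]:
        t = {a: MULTINOMIAL for a in self.anchor_names}
        t.update({v: CONTINUOUS for v in self.interest_names})
        return t


@dataclass
class GroundTruth:
    """A generating DAG (with latents) and its observed-margin MAG."""

    dag: MarkedGraph
    latents: tuple[str, ...]
    mag: MAG


def random_partially_ordered_mag(
    cfg: SimConfig, seed: int | np.random.Generator
) -> GroundTruth:
    """Draw one random ground truth respecting anchors < interest.

    Anchors are exogenous roots with ``anchor_children`` interest children
    each; interest-interest edges appear independently with
    ``interest_edge_prob`` along a random topological order; with
    probability ``latent_confounder_prob`` a latent parent of two random
    interest variables is added.  The observed MAG is the latent projection
    of the DAG.
    """
    rng = np.random.default_rng(seed)
    anchors = cfg.anchor_names
    interest = cfg.interest_names
    order = [interest[i] for i in rng.permutation(cfg.n_interest)]

    latents: list[str] = []
    if rng.random() < cfg.latent_confounder_prob:
        latents.append("L1")
    dag = MarkedGraph(anchors + interest + latents)
    for a in anchors:
        kids = rng.choice(interest, size=cfg.anchor_children, replace=False)
        for k in kids:
            dag.set_edge(a, k, TAIL, ARROWHEAD)
    for i in range(cfg.n_interest):
        for j in range(i + 1, cfg.n_interest):
            if rng.random() < cfg.interest_edge_prob:
                dag.set_edge(order[i], order[j], TAIL, ARROWHEAD)
    for lat in latents:
        pair = rng.choice(interest, size=2, replace=False)
        for v in pair:
            dag.set_edge(lat, v, TAIL, ARROWHEAD)
    mag = latent_project(dag, latents)
    return GroundTruth(dag=dag, latents=tuple(latents), mag=mag)


def sample_unique_mags(
    cfg: SimConfig, n: int, seed: int | np.random.Generator
) -> list[GroundTruth]:
    """Draw ``n`` ground truths with pairwise distinct observed skeletons
    (redraw on collision)."""
    rng = np.random.default_rng(seed)
    out: list[GroundTruth] = []
    seen: set[bytes] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("could not draw enough unique MAGs")
        gt = random_partially_ordered_mag(cfg, rng)
        key = (gt.mag.marks != 0).tobytes()
        if key in seen:
            continue
        seen.add(key)
        out.append(gt)
    return out


def simulate_mixed_dataset(
    gt: GroundTruth, N: int, cfg: SimConfig, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Sample N rows from a linear SEM on the generating DAG.

    Anchors are multinomial over levels {0,1,2}; continuous variables are
    linear in their parents plus Gaussian noise, with multinomial parents
    entering through per-level shifts (level 0 as reference).  Coefficient
    magnitudes are Uniform(coef_low, coef_high) with random sign, drawn per
    dataset.  Latents are simulated and dropped from the returned table.
    """
    rng = np.random.default_rng(seed)
    dag = gt.dag
    anchors = set(cfg.anchor_names)
    # topological order of the DAG
    import networkx as nx

    D = nx.DiGraph()
    D.add_nodes_from(dag.nodes)
    for i, j in dag.edges():
        (D.add_edge(i, j) if dag.mark(i, j) == ARROWHEAD else D.add_edge(j, i))
    topo = list(nx.topological_sort(D))

    def draw_coef(size=None):
        mag = rng.uniform(cfg.coef_low, cfg.coef_high, size=size)
        sign = rng.choice([-1.0, 1.0], size=size)
        return mag * sign

    values: dict[str, np.ndarray] = {}
    for v in topo:
        if v in anchors:
            values[v] = rng.choice(
                len(cfg.anchor_level_probs), size=N, p=cfg.anchor_level_probs
            ).astype(float)
            continue
        x = rng.normal(scale=cfg.noise_scale, size=N)
        for p in D.predecessors(v):
            if p in anchors:
                shifts = draw_coef(size=len(cfg.anchor_level_probs) - 1)
                lv = values[p].astype(int)
                x = x + np.where(lv > 0, shifts[np.clip(lv - 1, 0, None)], 0.0)
            else:
                x = x + draw_coef() * values[p]
        values[v] = x
    observed = cfg.anchor_names + cfg.interest_names
    return pd.DataFrame({v: values[v] for v in observed})


def true_pag(mag: MAG, config: DiscoveryConfig | None = None) -> PAG:
    """Maximally informative PAG of the MAG's Markov equivalence class,
    obtained by running the engine with the m-separation oracle and no
    background knowledge."""
    return run_discovery(oracle_ci(mag), mag.nodes, config).pag


def score(
    inferred: MarkedGraph,
    true_mag: MAG,
    interest: Sequence[str],
    base: int | None = None,
) -> int:
    """SHD-difference score over interest-variable edges.

    ``shd(inferred, true MAG) - shd(true MEC PAG, true MAG)``; pass the
    second term as ``base`` to avoid recomputing the true PAG.
    """
    if base is None:
        base = shd(true_pag(true_mag), true_mag, interest)
    return shd(inferred, true_mag, interest) - base


# ---------------------------------------------------------------------------
# benchmark


def run_benchmark(
    cfg: SimConfig | None = None,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    max_cond_size: int | None = None,
    screen_alpha: float = 1e-5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired comparison of conservative RFCI and anchorFCI.

    For every MAG x dataset x sample size, both algorithms run on the same
    data (sharing one cached tester) and are scored by the SHD-difference
    over interest-variable edges.  Returns ``(records, summary)``:
    per-run records and a per-N summary with mean +/- SD scores, the
    [min, max] range of per-MAG mean scores, the mean number of selected
    reliable anchors, the mean paired difference, and the one-sided
    Wilcoxon signed-rank p-value for "RFCI score exceeds anchorFCI score".
    """
    cfg = cfg or SimConfig()
    master = np.random.default_rng(seed)
    truths = sample_unique_mags(cfg, cfg.n_mags, master)
    roles = cfg.roles()
    types = cfg.types()
    interest = list(roles.interest)

    rows = []
    for mag_id, gt in enumerate(truths):
        tp = true_pag(gt.mag)
        base = shd(tp, gt.mag, interest)
        for rep in range(cfg.n_datasets):
            for N in cfg.sample_sizes:
                data_seed = int(master.integers(2**31 - 1))
                data = simulate_mixed_dataset(gt, N, cfg, data_seed)
                try:
                    tester = MixedCITester(data, types)
                except Exception as exc:
                    logger.warning(
                        "dataset (mag=%d rep=%d N=%d) unusable: %s",
                        mag_id, rep, N, exc,
                    )
                    continue
                row = {
                    "mag": mag_id, "rep": rep, "N": N,
                    "base_shd": base, "seed": data_seed,
                }
                try:
                    rfci = ConservativeRFCI(
                        alpha=alpha, max_cond_size=max_cond_size
                    ).fit(tester=tester)
                    row["rfci_score"] = score(rfci.pag_, gt.mag, interest, base)
                    anchor = AnchorFCI(
                        alpha=alpha,
                        max_cond_size=max_cond_size,
                        screen_alpha=screen_alpha,
                    ).fit(tester=tester, roles=roles)
                    row["anchorfci_score"] = score(
                        anchor.pag_, gt.mag, interest, base
                    )
                    row["n_anchors"] = len(anchor.anchors_)
                except Exception as exc:
                    logger.warning(
                        "run failed (mag=%d rep=%d N=%d): %s", mag_id, rep, N, exc
                    )
                    row["error"] = str(exc)
                rows.append(row)
    records = pd.DataFrame(rows)
    return records, summarize_benchmark(records)


def summarize_benchmark(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-run benchmark records into a per-sample-size table."""
    ok = records.dropna(subset=["rfci_score", "anchorfci_score"])
    out = []
    for N, grp in ok.groupby("N"):
        per_mag_rfci = grp.groupby("mag")["rfci_score"].mean()
        per_mag_anchor = grp.groupby("mag")["anchorfci_score"].mean()
        diff = grp["rfci_score"] - grp["anchorfci_score"]
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(
                stats.wilcoxon(diff, alternative="greater", zero_method="wilcox").pvalue
            )
        out.append(
            {
                "N": int(N),
                "rfci_min": per_mag_rfci.min(),
                "rfci_max": per_mag_rfci.max(),
                "rfci_mean": grp["rfci_score"].mean(),
                "rfci_sd": grp["rfci_score"].std(),
                "anchorfci_min": per_mag_anchor.min(),
                "anchorfci_max": per_mag_anchor.max(),
                "anchorfci_mean": grp["anchorfci_score"].mean(),
                "anchorfci_sd": grp["anchorfci_score"].std(),
                "n_anchors_mean": grp["n_anchors"].mean(),
                "diff_mean": diff.mean(),
                "wilcoxon_p": p,
                "n_runs": len(grp),
            }
        )
    return pd.DataFrame(out).sort_values("N").reset_index(drop=True)
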