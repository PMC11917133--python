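"""Permutation tests: genome-wide FST significance and OGD-sweep association.

Both use the +1-corrected permutation p-value
p = (1 + #{null >= observed}) / (reps + 1), which is never exactly zero;
at 1,000 replications the smallest reportable value is 1/1001, i.e.
"p < 0.001" means the observed statistic beat every null draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, PopulationMap, VariantTable
from .windows import wc_site_components, wc_theta_from_components


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    seed: int

    @property
    def reps(self) -> int:
        return len(self.null)


def _perm_p(observed: float, null: np.ndarray) -> float:
    return (1.0 + float((null >= observed).sum())) / (len(null) + 1.0)


def fst_label_permutation(vt: VariantTable, pm: PopulationMap, popA: str,
                          popB: str, reps: int = 100,
                          seed: int = 0) -> PermutationResult:
    """Genome-wide Weir-Cockerham theta against a label-shuffling null.

    Each replicate permutes the population labels over the pooled samples
    (group sizes preserved) and recomputes theta; the one-sided p asks
    whether the observed differentiation exceeds the exchangeable null.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sA = pm.samples_for(popA)
    sB = pm.samples_for(popB)
    if len(sA) < 2 or len(sB) < 2:
        raise ValueError("need >= 2 samples per population")
    sub = vt.subset_samples(sA + sB)
    g = sub.genotypes
    nA = len(sA)
    idx = np.arange(g.shape[1])

    def theta(perm):
        a, b, c = wc_site_components(g[:, perm[:nA]], g[:, perm[nA:]])
        return wc_theta_from_components(a, b, c)

    observed = theta(idx)
    rng = np.random.default_rng(seed)
    null = np.array([theta(rng.permutation(idx)) for _ in range(reps)])
    return PermutationResult(observed, null, _perm_p(observed, null), seed)


def ogd_sweep_association(n_windows: int, ogd: set, sweep_windows: set,
                          reps: int = 1000, seed: int = 0) -> PermutationResult:
    """Overlap of OGD windows with sweep-target windows vs uniform placement.

    The null redraws |sweep_windows| windows uniformly without replacement
    from the universe of ``n_windows`` window ids (0..n-1) and counts the
    intersection with the OGD set; one-sided p for overlap >= observed.
    The null is exchangeable uniform placement, so the p-value converges
    to the hypergeometric tail as reps grows.
    """
    ogd = set(ogd)
    sweep_windows = set(sweep_windows)
    if len(sweep_windows) > n_windows:
        raise ValueError("more sweep windows than windows in the universe")
    if not ogd <= set(range(n_windows)) or not sweep_windows <= set(range(n_windows)):
        raise ValueError("window ids must lie in the universe 0..n_windows-1")
    observed = float(len(ogd & sweep_windows))
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_windows, dtype=bool)
    mask[list(ogd)] = True
    s = len(sweep_windows)
    if s == 0:
        null = np.zeros(reps)
    else:
        null = np.array([
            mask[rng.choice(n_windows, size=s, replace=False)].sum()
            for _ in range(reps)
        ], dtype=float)
    return PermutationResult(observed, null, _perm_p(observed, null), seed)
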