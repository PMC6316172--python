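"""Possible-interaction inference from multi-condition expression data.

For every unordered gene pair one Pearson coefficient is computed per
dataset (datasets correspond to distinct culture conditions).  A pair is
called *possible and positive* when at least one coefficient reaches the
threshold and a strict majority of the remaining defined coefficients is
positive; *possible and negative* mirrors this below the negated threshold.
When both signs trigger, the majority over all defined coefficients rules.
Correlation does not orient an edge, so every call emits both directions as
optional interactions.

``find_max_threshold`` searches the largest threshold whose induced abstract
network still satisfies the experimental constraints -- the smallest
candidate-model space consistent with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import AbstractNetwork, Component, Interaction
from .synthesis import (INDETERMINATE, SATISFIABLE, SynthesisResult,
                        synthesize)


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix for one culture condition."""
    matrix: pd.DataFrame
    condition_label: str = ""
    source_label: str = ""

    def __post_init__(self):
        if self.matrix.shape[1] < 2:
            raise ValueError("an expression dataset needs >= 2 samples")


Pair = Tuple[str, str]


@dataclass
class CorrelationProfile:
    genes: List[str]
    n_datasets: int
    # per unordered pair: one coefficient per dataset, NaN where undefined
    coefficients: Dict[Pair, np.ndarray] = field(default_factory=dict)

    def pair(self, a: str, b: str) -> np.ndarray:
        return self.coefficients[(a, b) if a <= b else (b, a)]


def compute_correlation_profiles(datasets: Sequence[ExpressionDataset],
                                 log10_transform: bool = True
                                 ) -> CorrelationProfile:
    """One Pearson coefficient per gene pair per dataset.

    Expression is log10-transformed by default before correlating: levels
    span orders of magnitude, and on the linear scale the high-expression
    mode's multiplicative noise would dominate the coefficient.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    genes = list(datasets[0].matrix.index)
    for ds in datasets[1:]:
        if list(ds.matrix.index) != genes:
            raise ValueError("gene sets differ between datasets")
    n = len(datasets)
    profile = CorrelationProfile(genes, n)
    mats = []
    for ds in datasets:
        mat = ds.matrix
        if log10_transform:
            if (mat.to_numpy() <= 0).any():
                raise ValueError("log10 transform requires positive values")
            mat = np.log10(mat)
        # rows = genes; pandas leaves NaN where a gene is constant
        mats.append(mat.T.corr(method="pearson"))
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            coeffs = np.array([m.loc[a, b] for m in mats], dtype=float)
            profile.coefficients[(a, b) if a <= b else (b, a)] = coeffs
    return profile


def _call_sign(coeffs: np.ndarray, threshold: float) -> Optional[bool]:
    """True = positive call, False = negative, None = no call."""
    defined = coeffs[~np.isnan(coeffs)]
    if defined.size == 0:
        return None
    pos_trigger = bool((defined >= threshold).any())
    neg_trigger = bool((defined <= -threshold).any())
    if pos_trigger and neg_trigger:
        # conflicting triggers: the majority over all defined coefficients rules
        n_pos = int((defined > 0).sum())
        n_neg = int((defined < 0).sum())
        if n_pos > n_neg:
            return True
        if n_neg > n_pos:
            return False
        return None
    # "at least one coefficient over the threshold, and a strict majority of
    # the remaining ones of matching sign": the single triggering (extreme)
    # coefficient is set aside and the rest vote
    if pos_trigger:
        rest = np.delete(defined, int(np.argmax(defined)))
        if rest.size == 0 or (rest > 0).sum() * 2 > rest.size:
            return True
        return None
    if neg_trigger:
        rest = np.delete(defined, int(np.argmin(defined)))
        if rest.size == 0 or (rest < 0).sum() * 2 > rest.size:
            return False
        return None
    return None


def call_possible_interactions(profile: CorrelationProfile,
                               threshold: float) -> List[Interaction]:
    """Bidirectional optional interactions called at a threshold.

    Threshold comparisons are inclusive.  Self-interactions are never called.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    out: List[Interaction] = []
    for (a, b), coeffs in sorted(profile.coefficients.items()):
        sign = _call_sign(coeffs, threshold)
        if sign is None:
            continue
        out.append(Interaction(a, b, sign, definite=False))
        out.append(Interaction(b, a, sign, definite=False))
    return out


def default_candidate_grid(profile: CorrelationProfile) -> List[float]:
    """Sorted distinct absolute coefficients, restricted to (0, 1)."""
    vals = np.concatenate(list(profile.coefficients.values())) \
        if profile.coefficients else np.array([])
    vals = np.abs(vals[~np.isnan(vals)])
    grid = sorted({float(v) for v in vals if 0 < v < 1})
    return grid


class ThresholdSearchError(RuntimeError):
    def __init__(self, msg: str, violated: Optional[str] = None):
        super().__init__(msg)
        self.violated = violated


def induced_network(base: AbstractNetwork, profile: CorrelationProfile,
                    threshold: float) -> AbstractNetwork:
    """Base roster + definite interactions, plus the called optional ones.

    Called edges that duplicate a definite interaction (same source, target
    and sign) are dropped; gene components of the base network keep their
    allowed conditions.
    """
    definite = base.definite_interactions
    have = {(i.source, i.target, i.positive) for i in definite}
    called = [i for i in call_possible_interactions(profile, threshold)
              if (i.source, i.target, i.positive) not in have
              and i.source in base and i.target in base
              and base.component(i.target).role != "signal"]
    return AbstractNetwork(base.components, definite + called)


def find_max_threshold(datasets: Sequence[ExpressionDataset],
                       base: AbstractNetwork,
                       constraints: Sequence,
                       candidate_grid: Optional[Sequence[float]] = None,
                       timeout: float = 300.0
                       ) -> Tuple[float, AbstractNetwork, SynthesisResult]:
    """Largest candidate threshold whose induced ABN satisfies the constraints.

    Lowering the threshold only adds optional interactions, so satisfiability
    is monotone in the threshold; the scan walks the grid downwards and stops
    at the first satisfiable ABN.
    """
    profile = compute_correlation_profiles(datasets)
    grid = sorted(candidate_grid) if candidate_grid is not None \
        else default_candidate_grid(profile)
    if not grid:
        raise ThresholdSearchError("empty candidate threshold grid")
    for th in reversed(grid):
        net = induced_network(base, profile, th)
        res = synthesize(net, constraints, timeout)
        if res.status == SATISFIABLE:
            return th, net, res
        if res.status == INDETERMINATE:
            raise ThresholdSearchError(
                f"solver budget exhausted at threshold {th}")
    # unsatisfiable even at the minimum: identify the first violated constraint
    net = induced_network(base, profile, grid[0])
    acc = []
    for con in constraints:
        acc.append(con)
        if synthesize(net, acc, timeout).status != SATISFIABLE:
            name = getattr(con, "name", str(con))
            raise ThresholdSearchError(
                f"constraints unsatisfiable even at minimum threshold "
                f"{grid[0]}; first violated constraint: {name}", violated=name)
    raise ThresholdSearchError("constraints unsatisfiable at minimum "
                               "threshold, but satisfiable incrementally "
                               "(inconsistent solver behaviour)")
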