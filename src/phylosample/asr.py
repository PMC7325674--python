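"""Ancestral character state reconstruction of a discrete lifestyle trait.

The trait — a fungal lifestyle in ten categories (lichenized,
rock-inhabiting, plant pathogen, saprotroph, epiphyte, animal pathogen,
fungal pathogen, ectomycorrhizal, endophyte, extremophile) — evolves on a
rooted phylogeny.  Two reconstructions of the basal (root) node are
provided:

* maximum likelihood under the one-parameter Markov k-state model (Mk1),
  the k-state generalization of Jukes–Cantor: a single rate β between every
  ordered pair of states, P_ii(t) = 1/k + (k−1)/k·e^{−kβt},
  P_ij(t) = 1/k − 1/k·e^{−kβt}.  The per-state root log-likelihoods are
  conditional on the root state (no prior folded in); the overall
  log-likelihood places a uniform prior on the root state.  A "best state"
  set collects all states within a log-likelihood threshold (default 2.0)
  of the maximum, the conventional support cutoff for reporting
  reconstructed states.
* maximum parsimony via Sankoff dynamic programming with unit costs
  (equivalent to Fitch on binary trees), returning the set of minimal-cost
  root states and the minimal number of changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .tree import PhyloTree

LIFESTYLE_NAMES = ("LIC", "RIF", "PP", "SAP", "EPI", "AP", "FP", "ECT", "END", "EXT")


@dataclass
class CharacterMap:
    """Taxon → discrete state in {0..k−1}."""

    states: dict[str, int]
    k: int = 10
    state_names: tuple[str, ...] = LIFESTYLE_NAMES

    def __post_init__(self):
        if not 2 <= self.k <= 64:
            raise ValueError("k must be in [2, 64]")
        if len(self.state_names) != self.k:
            self.state_names = tuple(f"S{i}" for i in range(self.k))
        bad = {t: s for t, s in self.states.items() if not 0 <= s < self.k}
        if bad:
            raise ValueError(f"states out of range [0, {self.k}): {bad}")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = 10,
                 state_names: Sequence[str] = LIFESTYLE_NAMES) -> "CharacterMap":
        states: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    taxon, state = line.split("\t")
                    states[taxon] = int(state)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: expected 'taxon<TAB>state'") from None
        return cls(states, k=k, state_names=tuple(state_names))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon, state in self.states.items():
                fh.write(f"{taxon}\t{state}\n")


@dataclass
class Mk1Model:
    k: int
    beta: float

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class AsrResult:
    root_logliks: np.ndarray  # length k, conditional on root state
    beta_hat: float
    best_states: list[int]
    parsimony_states: set[int]
    parsimony_score: int
    state_names: tuple[str, ...] = LIFESTYLE_NAMES
    boundary_fit: bool = False

    @property
    def total_loglik(self) -> float:
        """Log-likelihood under a uniform root prior."""
        return float(logsumexp(self.root_logliks) - math.log(len(self.root_logliks)))


def mk1_transition_matrix(model: Mk1Model, t: float) -> np.ndarray:
    """Mk1 transition probabilities over a branch of length t."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    k = model.k
    e = math.exp(-k * model.beta * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    return P


def _check_mapped(tree: PhyloTree, chars: CharacterMap) -> None:
    unmapped = [n.name for n in tree.leaves() if n.name not in chars.states]
    if unmapped:
        raise ValueError(f"leaves without a character state: {unmapped}")


def mk1_root_logliks(tree: PhyloTree, chars: CharacterMap, model: Mk1Model) -> np.ndarray:
    """Per-root-state conditional log-likelihoods by Felsenstein pruning.

    Entry s is log P(tip states | root state = s); no root prior is folded
    in, matching the per-state values reported for a basal node.
    """
    if not tree.is_rooted:
        raise ValueError("ancestral state reconstruction needs a rooted tree")
    _check_mapped(tree, chars)
    k = model.k
    cond: dict[int, np.ndarray] = {}
    scale: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = np.zeros(k)
            c[chars.states[node.name]] = 1.0
            cond[id(node)], scale[id(node)] = c, 0.0
            continue
        c = np.ones(k)
        logs = 0.0
        for child in node.children:
            P = mk1_transition_matrix(model, child.length or 0.0)
            c = c * (P @ cond.pop(id(child)))
            logs += scale.pop(id(child))
        top = c.max()
        if top > 0:
            c = c / top
            logs += math.log(top)
        cond[id(node)], scale[id(node)] = c, logs
    root_c = cond[id(tree.root)]
    with np.errstate(divide="ignore"):
        return np.log(root_c) + scale[id(tree.root)]


def mk1_total_loglik(tree: PhyloTree, chars: CharacterMap, model: Mk1Model) -> float:
    """Uniform-root-prior log-likelihood of the trait on the tree."""
    return float(logsumexp(mk1_root_logliks(tree, chars, model)) - math.log(model.k))


def fit_mk1(
    tree: PhyloTree, chars: CharacterMap, threshold: float = 2.0
) -> tuple[float, AsrResult]:
    """Maximum-likelihood Mk1 rate and the full root reconstruction.

    β is optimized by bounded Brent search on log10 β ∈ [−6, 2] of the
    uniform-prior total log-likelihood; the per-state root log-likelihoods
    are then evaluated once at the fitted rate (not re-fitted per state).
    A fit at the search boundary (e.g. a constant trait driving β → 0) is
    flagged, not fatal.
    """
    if not tree.is_rooted:
        raise ValueError("ancestral state reconstruction needs a rooted tree")
    _check_mapped(tree, chars)
    if tree.total_branch_length() <= 0:
        raise ValueError("tree has no positive branch length")
    k = chars.k

    def neg(log10_beta: float) -> float:
        return -mk1_total_loglik(tree, chars, Mk1Model(k, 10.0**log10_beta))

    res = minimize_scalar(neg, bounds=(-6.0, 2.0), method="bounded",
                          options={"xatol": 1e-7})
    log10_beta = float(res.x)
    boundary = log10_beta < -5.9 or log10_beta > 1.9
    beta_hat = 10.0**log10_beta
    logliks = mk1_root_logliks(tree, chars, Mk1Model(k, beta_hat))
    p_states, p_score = parsimony_root_states(tree, chars)
    result = AsrResult(
        root_logliks=logliks,
        beta_hat=beta_hat,
        best_states=best_states(logliks, threshold),
        parsimony_states=p_states,
        parsimony_score=p_score,
        state_names=chars.state_names,
        boundary_fit=boundary,
    )
    return beta_hat, result


def parsimony_root_states(tree: PhyloTree, chars: CharacterMap) -> tuple[set[int], int]:
    """Sankoff parsimony with unit costs (Fitch-equivalent on binary trees).

    Returns the set of root states attaining the minimal number of changes,
    and that minimal count.
    """
    if not tree.is_rooted:
        raise ValueError("ancestral state reconstruction needs a rooted tree")
    _check_mapped(tree, chars)
    k = chars.k
    big = np.inf
    cost: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = np.full(k, big)
            c[chars.states[node.name]] = 0.0
            cost[id(node)] = c
            continue
        total = np.zeros(k)
        for child in node.children:
            cc = cost.pop(id(child))
            # min over child state of (cost + 1 if change else 0)
            stay = cc
            move = cc.min() + 1.0
            total += np.minimum(stay, move)
        cost[id(node)] = total
    root_cost = cost[id(tree.root)]
    score = root_cost.min()
    states = {int(s) for s in np.flatnonzero(root_cost <= score + 1e-9)}
    return states, int(round(score))


def best_states(root_logliks: Sequence[float], threshold: float = 2.0) -> list[int]:
    """States within `threshold` log units of the best root log-likelihood.

    This is the asterisk rule used when reporting reconstructed states in a
    per-state likelihood table: every state whose log-likelihood is within
    the threshold of the maximum is reported as a credible ancestral state.
    """
    logliks = np.asarray(root_logliks, dtype=float)
    if not np.isfinite(logliks).any():
        raise ValueError("no state has finite log-likelihood")
    top = np.nanmax(logliks[np.isfinite(logliks)])
    return [int(s) for s in np.flatnonzero(top - logliks <= threshold)]
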