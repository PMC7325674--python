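"""Synthetic study fixtures: species trees, gene alignments, lifestyle traits.

Emulates the statistical structure of a genome-scale single-copy-ortholog
dataset over a fungal class: a birth–death species tree over tens of taxa, a
few hundred unlinked gene alignments with heterogeneous lengths simulated on
that tree, per-taxon-per-gene missingness (up to 90% for poorly assembled
taxa), and a 10-state discrete lifestyle trait evolved on the same tree
under the Mk1 model.  Everything is reproducible from a manifest of
parameters and seeds.

Gene trees equal the species tree (no coalescent discordance): the stages
tested downstream — column resampling, RF comparison, ancestral state
reconstruction — operate on a supermatrix and a fixed phylogeny and do not
require discordance; this is a documented limitation, not an omission.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .alignment_io import GeneAlignment
from .asr import CharacterMap, Mk1Model, mk1_transition_matrix
from .tree import Node, PhyloTree, parse_newick, write_newick

BASES = "ACGT"


def derive_seed(*parts: int) -> int:
    """Stable 31-bit seed derived from integer parts (for replicate streams)."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0]) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    depth: float = 0.5,
) -> PhyloTree:
    """Birth–death species tree conditioned on `n_taxa` extant tips.

    Simulation is delegated to dendropy's birth–death sampler; branch
    lengths are rescaled so the maximum root-to-tip path equals `depth`
    substitutions/site (0.5 by default, a deep class-level divergence).
    Leaves are labelled T1..Tn.  Deterministic per seed.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    from dendropy.simulate import treesim

    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    tree = parse_newick(dtree.as_string(schema="newick", suppress_rooting=True))
    _rescale_depth(tree, depth)
    tree.validate()
    return tree


def _rescale_depth(tree: PhyloTree, depth: float) -> None:
    def max_depth(node: Node) -> float:
        below = max((max_depth(c) for c in node.children), default=0.0)
        return below + (node.length or 0.0)

    current = max((max_depth(c) for c in tree.root.children), default=0.0)
    if current <= 0:
        raise ValueError("tree has zero depth")
    factor = depth / current
    for node in tree.postorder():
        if node is not tree.root and node.length is not None:
            node.length *= factor


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix normalized to one expected substitution per unit time."""
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(freqs * np.diag(Q)).sum()
    return Q / rate


def _transition_for(model: str, kappa: float, freqs: np.ndarray, t: float) -> np.ndarray:
    if model == "JC":
        e = np.exp(-4.0 / 3.0 * t)
        P = np.full((4, 4), 0.25 * (1.0 - e))
        np.fill_diagonal(P, 0.25 + 0.75 * e)
        return P
    from scipy.linalg import expm

    return expm(_hky_rate_matrix(kappa, freqs) * t)


def simulate_alignment(
    tree: PhyloTree,
    length: int,
    model: str = "JC",
    seed: int = 0,
    kappa: float = 2.0,
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    gene_id: str = "gene",
) -> GeneAlignment:
    """Evolve an alignment down the tree, sites independent.

    The root sequence is drawn from the stationary frequencies; each branch
    applies its transition matrix to every site.  model is "JC" or "HKY"
    (kappa, base_freqs).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if model not in ("JC", "HKY"):
        raise ValueError(f"unknown model {model!r}")
    freqs = np.asarray(base_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(4, size=length, p=freqs)
    }
    leaf_rows: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is not tree.root:
            P = _transition_for(model, kappa, freqs, node.length or 0.0)
            parent_states = states[id(node.parent)]
            cum = P.cumsum(axis=1)
            u = rng.random(length)
            child = (u[:, None] > cum[parent_states]).sum(axis=1)
            states[id(node)] = child.astype(np.int64)
        if node.is_leaf:
            leaf_rows[node.name] = states[id(node)]
    taxa = sorted(leaf_rows)
    codes = np.stack([leaf_rows[t] for t in taxa]).astype(np.uint8)
    return GeneAlignment(gene_id, taxa, codes)


def default_length_sampler(rng: np.random.Generator) -> int:
    """Log-normal gene length, mean ≈ 1657 bp (genome-scale ortholog set:
    hundreds of genes summing to ~1 Mb), floor 100 bp."""
    return max(100, int(rng.lognormal(mean=7.2328, sigma=0.6)))


def simulate_gene_set(
    tree: PhyloTree,
    n_genes: int,
    length_sampler: Callable[[np.random.Generator], int] | None = None,
    missing_frac: Mapping[str, float] | float = 0.0,
    seed: int = 0,
    model: str = "JC",
) -> tuple[list[GeneAlignment], list[str]]:
    """Unlinked genes on a shared topology, with per-taxon gene missingness.

    For each gene and taxon an independent Bernoulli(missing_frac[taxon])
    draw removes that taxon's row from the gene, emulating heterogeneous
    assembly completeness.  Returns the genes and a list of warnings (taxa
    that ended up absent from every gene).
    """
    sampler = length_sampler or default_length_sampler
    taxa = sorted(tree.leaf_set())
    if isinstance(missing_frac, (int, float)):
        miss = {t: float(missing_frac) for t in taxa}
    else:
        miss = {t: float(missing_frac.get(t, 0.0)) for t in taxa}
    bad = {t: f for t, f in miss.items() if not 0.0 <= f <= 0.9}
    if bad:
        raise ValueError(f"missing fractions must be in [0, 0.9]: {bad}")

    genes: list[GeneAlignment] = []
    seen: set[str] = set()
    for g in range(n_genes):
        rng = np.random.default_rng(derive_seed(seed, 1, g))
        length = sampler(rng)
        aln = simulate_alignment(tree, length, model=model,
                                 seed=derive_seed(seed, 2, g), gene_id=f"gene{g + 1:04d}")
        keep = [t for t in aln.taxa if rng.random() >= miss[t]]
        if len(keep) < 2:
            keep = sorted(aln.taxa)[:2]  # keep genes minimally informative
        genes.append(aln.subset_taxa(keep))
        seen.update(keep)
    warnings = [f"taxon {t} absent from every gene" for t in taxa if t not in seen]
    return genes, warnings


def simulate_discrete_trait(
    tree: PhyloTree, k: int = 10, beta: float = 0.5, seed: int = 0
) -> tuple[CharacterMap, dict[str, int], int]:
    """Evolve a k-state trait under Mk1 down the tree.

    Root state uniform on {0..k−1}.  Returns the tip CharacterMap, the true
    internal node states keyed by the sorted-leaf-set label of each internal
    node, and the true root state.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(seed)
    model = Mk1Model(k, beta)
    node_state: dict[int, int] = {id(tree.root): int(rng.integers(k))}
    tips: dict[str, int] = {}
    internal: dict[str, int] = {}

    def leafset_label(node: Node) -> str:
        return ",".join(sorted(n.name for n in PhyloTree(node).leaves()))

    for node in tree.preorder():
        if node is not tree.root:
            P = mk1_transition_matrix(model, node.length or 0.0)
            parent = node_state[id(node.parent)]
            node_state[id(node)] = int(rng.choice(k, p=P[parent]))
        if node.is_leaf:
            tips[node.name] = node_state[id(node)]
        else:
            internal[leafset_label(node)] = node_state[id(node)]
    root_state = node_state[id(tree.root)]
    return CharacterMap(tips, k=k), internal, root_state


# ---------------------------------------------------------------------------
# study fixtures
# ---------------------------------------------------------------------------

PROFILES = {
    # a few poorly assembled taxa carry heavy missingness (up to 0.9), the
    # rest light, mirroring heterogeneous genome assembly completeness
    "small": {"n_taxa": 12, "n_genes": 50, "n_poor_taxa": 1, "poor_missing": 0.6,
              "base_missing": 0.05, "k": 10, "trait_beta": 0.5,
              "mean_gene_length": 400.0},
    "paper-like": {"n_taxa": 48, "n_genes": 200, "n_poor_taxa": 4, "poor_missing": 0.9,
                   "base_missing": 0.1, "k": 10, "trait_beta": 0.5,
                   "mean_gene_length": 1657.0},
}


@dataclass
class StudyFixture:
    true_tree: PhyloTree
    genes: list[GeneAlignment]
    traits: CharacterMap
    manifest: dict = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.true_tree.leaf_set())


def generate_fixture_study(
    profile: str = "paper-like", seed: int = 0, out_dir: str | Path | None = None
) -> StudyFixture:
    """Generate a complete study fixture for a named profile.

    Profiles: "small" (12 taxa, 50 genes) for fast tests; "paper-like"
    (48 taxa, 200 genes, missingness up to 0.9, 10-state trait) matching
    the structure of a genome-scale ortholog dataset at desk scale.  If
    `out_dir` is given, writes one FASTA per gene, the truth tree (newick),
    the trait table (TSV) and a JSON manifest sufficient to regenerate the
    fixture bit-identically.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}")
    p = PROFILES[profile]
    tree = simulate_tree(p["n_taxa"], seed=derive_seed(seed, 10))
    taxa = sorted(tree.leaf_set())

    rng = np.random.default_rng(derive_seed(seed, 11))
    poor = sorted(rng.choice(taxa, size=p["n_poor_taxa"], replace=False).tolist())
    missing = {t: (p["poor_missing"] if t in poor else p["base_missing"]) for t in taxa}

    mu = float(np.log(p["mean_gene_length"]) - 0.18)  # lognormal sigma=0.6

    def sampler(r: np.random.Generator) -> int:
        return max(100, int(r.lognormal(mean=mu, sigma=0.6)))

    genes, warnings = simulate_gene_set(
        tree, p["n_genes"], length_sampler=sampler, missing_frac=missing,
        seed=derive_seed(seed, 12),
    )
    traits, _internal, root_state = simulate_discrete_trait(
        tree, k=p["k"], beta=p["trait_beta"], seed=derive_seed(seed, 13)
    )
    manifest = {
        "profile": profile,
        "seed": seed,
        "parameters": {k2: v for k2, v in p.items()},
        "poor_taxa": poor,
        "true_root_state": root_state,
        "warnings": warnings,
        "n_taxa": len(taxa),
        "n_genes": len(genes),
        "total_length": int(sum(g.length for g in genes)),
    }
    fixture = StudyFixture(tree, genes, traits, manifest)
    if out_dir is not None:
        write_fixture(fixture, out_dir)
    return fixture


def write_fixture(fixture: StudyFixture, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    for gene in fixture.genes:
        with open(out / "genes" / f"{gene.gene_id}.fasta", "w") as fh:
            for taxon, seq in gene.seqs.items():
                fh.write(f">{taxon}\n{seq}\n")
    with open(out / "true_tree.nwk", "w") as fh:
        fh.write(write_newick(fixture.true_tree) + "\n")
    fixture.traits.to_tsv(out / "traits.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(fixture.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
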