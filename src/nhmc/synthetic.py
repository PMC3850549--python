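"""Synthetic benchmark generator: hierarchies, labelled datasets, networks.

The generator emulates the structure of gene-function prediction benchmarks:
a FunCat-like class tree (optionally made GO-like by adding second parents),
examples whose ancestor-closed label sets are drawn by top-down Bernoulli
path sampling, continuous/discrete attributes that carry a tunable amount of
class signal, and a planted-partition interaction network in which pairs of
examples sharing a most-specific class are linked with probability ``p_in``
and all other pairs with ``p_out`` — the guilt-by-association structure that
makes functional annotations autocorrelated across interacting proteins.

Sharing is tested on *most-specific* classes (not any ancestor) so the
planted autocorrelation is strongest for the deepest, most fragmented
classes, mirroring the locality of autocorrelation at lower hierarchy
levels.  The single global seed fans out into independent sub-streams for
labels, attributes and network draws, so, e.g., adding attributes does not
perturb the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import HMCDataset
from .hierarchy import ClassHierarchy
from .network import Network

__all__ = ["SynthConfig", "gen_hierarchy", "gen_dataset", "gen_network", "generate"]


@dataclass
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give a 14-class depth-3 binary tree over 200 examples with
    moderately informative attributes and a clearly guilt-by-association
    network (``p_in`` an order of magnitude above ``p_out``), small label
    noise, and a strict tree hierarchy.
    """

    depth: int = 3                 #: hierarchy depth D (levels below the root)
    branching: int = 2             #: children per class
    n: int = 200                   #: number of examples
    m_cont: int = 10               #: continuous attributes
    m_disc: int = 2                #: discrete attributes (3 categories each)
    pi_child: float = 0.5          #: P(class kept | parent kept); also top-level rate
    delta: float = 1.0             #: mean shift of informative attributes for positives
    attrs_per_class: int = 2       #: continuous attributes shifted per class
    p_in: float = 0.25             #: edge prob. for pairs sharing a most-specific class
    p_out: float = 0.02            #: edge prob. for all other pairs
    rho: float = 0.05              #: label-bit flip probability (re-closed afterwards)
    dag_prob: float = 0.0          #: prob. of a second parent (GO-like DAG); 0 = tree
    w0: float = 0.75               #: hierarchy weight decay
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not 0.0 <= self.rho < 0.5:
            raise ValueError("need 0 <= rho < 0.5")
        if self.depth < 1 or self.branching < 1:
            raise ValueError("depth and branching must be >= 1")

    def _streams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        names = ("hierarchy", "labels", "attributes", "network")
        return {
            name: np.random.default_rng(child)
            for name, child in zip(names, root.spawn(len(names)))
        }


def gen_hierarchy(cfg: SynthConfig) -> ClassHierarchy:
    """Complete ``branching``-ary class tree of depth ``depth``.

    With ``dag_prob > 0`` each class below the top level gains, with that
    probability, a second parent drawn from the previous level.
    """
    rng = cfg._streams()["hierarchy"]
    classes: list[str] = []
    parents: dict[str, list[str]] = {}
    levels: list[list[str]] = []
    prev: list[str] = []
    for d in range(1, cfg.depth + 1):
        level: list[str] = []
        slots = prev if prev else [None]
        for p in slots:
            for b in range(cfg.branching):
                name = f"{p}.{b + 1}" if p is not None else f"c{b + 1}"
                classes.append(name)
                parents[name] = [] if p is None else [p]
                level.append(name)
        levels.append(level)
        prev = level
    if cfg.dag_prob > 0:
        for d in range(1, len(levels)):
            for name in levels[d]:
                if rng.random() < cfg.dag_prob:
                    extra = str(rng.choice(levels[d - 1]))
                    if extra not in parents[name]:
                        parents[name].append(extra)
    return ClassHierarchy(classes, parents, w0=cfg.w0)


def _sample_labels(h: ClassHierarchy, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Top-down Bernoulli path sampling, then ancestor closure."""
    K = h.n_classes
    Y = np.zeros((cfg.n, K), dtype=np.uint8)
    top = [c for c in h.classes if not h.parents[c]]
    for i in range(cfg.n):
        kept: set[str] = set()
        frontier = [c for c in top if rng.random() < cfg.pi_child]
        while frontier:
            c = frontier.pop()
            kept.add(c)
            for ch in h.children(c):
                if ch not in kept and rng.random() < cfg.pi_child:
                    frontier.append(ch)
        Y[i] = h.close(kept)
    return Y


def gen_dataset(h: ClassHierarchy, cfg: SynthConfig) -> HMCDataset:
    """Labelled dataset with class-informative attributes and label noise.

    For each class, ``attrs_per_class`` randomly chosen continuous attributes
    have their mean shifted by ``delta`` for positive examples, on top of
    unit-variance Gaussian noise.  Each discrete attribute is tied to one
    class: positives draw its three categories from a tilted distribution,
    negatives uniformly.  Finally a fraction ``rho`` of label bits is
    flipped and the matrix re-closed, so noisy labels still satisfy the
    hierarchical constraint.
    """
    streams = cfg._streams()
    Y = _sample_labels(h, cfg, streams["labels"])
    rng = streams["attributes"]
    K = h.n_classes

    Xc = rng.standard_normal((cfg.n, cfg.m_cont)) if cfg.m_cont else np.zeros((cfg.n, 0))
    if cfg.m_cont:
        for k in range(K):
            cols = rng.choice(cfg.m_cont, size=min(cfg.attrs_per_class, cfg.m_cont), replace=False)
            pos = Y[:, k].astype(bool)
            for c in cols:
                Xc[pos, c] += cfg.delta

    cols: dict[str, object] = {f"x{j + 1}": Xc[:, j] for j in range(cfg.m_cont)}
    categories = ["a", "b", "c"]
    for j in range(cfg.m_disc):
        k = int(rng.integers(K))
        tilt_cat = int(rng.integers(len(categories)))
        probs = np.full(len(categories), (1.0 - 0.6) / (len(categories) - 1))
        probs[tilt_cat] = 0.6
        pos = Y[:, k].astype(bool)
        vals = np.empty(cfg.n, dtype=object)
        vals[pos] = rng.choice(categories, size=int(pos.sum()), p=probs)
        vals[~pos] = rng.choice(categories, size=int((~pos).sum()))
        cols[f"d{j + 1}"] = vals

    Y_true = Y
    if cfg.rho > 0:
        flips = rng.random(Y.shape) < cfg.rho
        Y = np.where(flips, 1 - Y, Y).astype(np.uint8)
        Y = h.close_bits(Y)

    X = pd.DataFrame(cols)
    ids = [f"g{i + 1}" for i in range(cfg.n)]
    return HMCDataset(X=X, Y=Y, ids=ids, hierarchy=h,
                      name=f"synthetic-seed{cfg.seed}", Y_true=Y_true)


def gen_network(dataset: HMCDataset, cfg: SynthConfig) -> Network:
    """Planted-partition interaction network over the dataset's examples.

    Each unordered pair is linked with probability ``p_in`` if the two
    examples share at least one most-specific class, else ``p_out``.
    Sharing is judged on the noise-free labels when the dataset carries them
    (``Y_true``): interactions reflect true function, while annotation noise
    lives in the observed labels — the situation that makes the interactome
    informative beyond the annotations themselves.
    """
    rng = cfg._streams()["network"]
    h = dataset.hierarchy
    n = dataset.n_examples
    base = dataset.Y if dataset.Y_true is None else dataset.Y_true
    M = np.zeros((n, h.n_classes), dtype=bool)
    for i in range(n):
        for c in h.most_specific(base[i]):
            M[i, h.index[c]] = True
    share = (M @ M.T) > 0
    draws = rng.random((n, n))
    net = Network()
    for i in range(n):
        for j in range(i + 1, n):
            p = cfg.p_in if share[i, j] else cfg.p_out
            if p > 0 and draws[i, j] < p:
                net.add_edge(dataset.ids[i], dataset.ids[j], 1.0)
    return net


def generate(cfg: SynthConfig) -> tuple[ClassHierarchy, HMCDataset, Network]:
    """Generate the full benchmark triple for one configuration."""
    h = gen_hierarchy(cfg)
    ds = gen_dataset(h, cfg)
    net = gen_network(ds, cfg)
    return h, ds, net
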