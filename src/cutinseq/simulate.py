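"""Synthetic cutin polymers, stochastic partial digestion, noisy spectra.

The simulator provides ground truth for end-to-end testing without any
external data.  A polymer is a tree of ester bonds (child carboxyl ->
parent hydroxyl site); partial enzymatic hydrolysis is modeled as
independent cleavage of each ester bond with probability ``p_cleave``
(hydrolysis form: acid + alcohol termini), and spectra are the predicted
ester-cleavage daughters of a fragment perturbed by Gaussian ppm mass error
plus uniform-random noise peaks in the instrument scan window.

Defaults emulate the measured system: monomer abundances follow the
qualitative ranking of apple cutin (six major monomers carrying ~80% of the
mass), 16-hydroxy-16:0 and 18-hydroxy-18:2 are up-weighted at omega termini
and 16-hydroxy-16:0 / 18-hydroxy-18:3 at carboxyl termini, mass error is a
few ppm and the scan window is m/z 100-1700.  All randomness flows from one
explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chem import AdductSpec, get_adduct
from .monomers import Monomer, MonomerCatalog
from .oligomers import Oligomer, precursor_mz, predict_ester_fragments
from .sequencing import Spectrum

__all__ = [
    "PolymerGraph",
    "SimulatedDigest",
    "build_polymer",
    "digest_polymer",
    "simulate_spectrum",
]

#: Qualitative abundance weights for the six dominant apple-cutin monomers
#: (together ~80% of the monomer pool); every other eligible acid shares the
#: remaining weight equally.  Exact proportions are a configuration choice
#: because only the ranking, not the numbers, is established.
DEFAULT_ABUNDANCE: dict[str, float] = {
    "9,10,18-trihydroxy-18:0": 20.0,
    "10,16-dihydroxy-16:0": 18.0,
    "9,10,18-trihydroxy-18:3": 12.0,
    "9,10,18-trihydroxy-18:2": 11.0,
    "18-hydroxy-18:2": 10.0,
    "9,10,18-trihydroxy-18:1": 9.0,
}

DEFAULT_OMEGA_TERMINAL = ("16-hydroxy-16:0", "18-hydroxy-18:2")
DEFAULT_CARBOXYL_TERMINAL = ("16-hydroxy-16:0", "18-hydroxy-18:3")


@dataclass(frozen=True)
class PolymerGraph:
    """A tree of ester bonds over monomer instances.

    ``edges`` holds ``(child, parent, site)`` triples: the carboxyl of node
    ``child`` esterifies hydroxyl ``site`` of node ``parent``.  Each
    carboxyl is used at most once (out-degree <= 1) and each hydroxyl site
    at most once; the root (out-degree 0) carries the free carboxyl.
    """

    monomers: tuple[Monomer, ...]
    edges: tuple[tuple[int, int, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.monomers)
        out_used: set[int] = set()
        sites_used: set[tuple[int, int]] = set()
        for child, parent, site in self.edges:
            if not (0 <= child < n and 0 <= parent < n) or child == parent:
                raise ValueError(f"bad edge ({child}, {parent}, {site})")
            if child in out_used:
                raise ValueError(f"monomer {child} uses its carboxyl in two ester bonds")
            out_used.add(child)
            if (parent, site) in sites_used:
                raise ValueError(f"hydroxyl site {site} of monomer {parent} used twice")
            sites_used.add((parent, site))
            if site not in self.monomers[parent].hydroxyls:
                raise ValueError(
                    f"site {site} is not a hydroxyl of {self.monomers[parent].id}"
                )
        # acyclicity: follow child->parent links; a cycle would revisit a node
        parent_of = {c: p for c, p, _ in self.edges}
        for start in range(n):
            seen = set()
            node = start
            while node in parent_of:
                if node in seen:
                    raise ValueError("ester-bond graph contains a cycle")
                seen.add(node)
                node = parent_of[node]

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def is_linear(self) -> bool:
        parents = [p for _, p, _ in self.edges]
        return len(parents) == len(set(parents))

    def monomer_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(m.id for m in self.monomers))

    def fragment_oligomer(self, nodes: list[int] | None = None) -> Oligomer:
        """Linearize (a subtree of) the graph into an ordered oligomer.

        Follows the free-carboxyl-first convention; a branched subtree is
        linearized along its longest carboxyl-to-omega path with a warning,
        since linear sequencing never sees branch topology.
        """
        node_set = set(range(len(self.monomers))) if nodes is None else set(nodes)
        edges = [(c, p, s) for c, p, s in self.edges if c in node_set and p in node_set]
        children: dict[int, list[tuple[int, int]]] = {}
        for child, parent, site in edges:
            children.setdefault(parent, []).append((child, site))
        # the root is the node whose carboxyl is free: no outgoing edge
        out_nodes = {c for c, _, _ in edges}
        roots = [n for n in sorted(node_set) if n not in out_nodes]
        if len(roots) != 1:
            raise ValueError(f"subtree must have exactly one free-carboxyl root, got {roots}")

        def longest_path(node: int) -> list[tuple[int, int | None]]:
            best: list[tuple[int, int | None]] = [(node, None)]
            for child, site in sorted(children.get(node, [])):
                tail = longest_path(child)
                candidate = [(node, site)] + tail
                if len(candidate) > len(best):
                    best = candidate
            return best

        branched = any(len(v) > 1 for v in children.values())
        if branched:
            warnings.warn(
                "branched subtree linearized along its longest carboxyl-to-omega path",
                stacklevel=2,
            )
        path = longest_path(roots[0])
        monomers = tuple(self.monomers[n] for n, _ in path)
        sites = tuple(site for _, site in path[:-1] if site is not None)
        return Oligomer(monomers, sites)


def _weights_for(pool: list[Monomer], weights: dict[str, float] | None) -> np.ndarray:
    table = DEFAULT_ABUNDANCE if weights is None else weights
    named_total = sum(v for k, v in table.items() if any(m.id == k for m in pool))
    others = [m for m in pool if m.id not in table]
    rest_each = (100.0 - named_total) / len(others) if others else 0.0
    w = np.array([table.get(m.id, rest_each) for m in pool], dtype=float)
    if not np.all(w > 0):
        w = np.clip(w, 1e-6, None)
    return w / w.sum()


def build_polymer(
    catalog: MonomerCatalog,
    n_monomers: int,
    terminal_bias: float = 5.0,
    branching_prob: float = 0.0,
    seed: int = 0,
    weights: dict[str, float] | None = None,
    omega_terminal_ids: tuple[str, ...] = DEFAULT_OMEGA_TERMINAL,
    carboxyl_terminal_ids: tuple[str, ...] = DEFAULT_CARBOXYL_TERMINAL,
) -> PolymerGraph:
    """Sample a random cutin polymer tree, reproducibly for a fixed seed.

    Internal positions are drawn from hydroxyl-bearing acids with abundance
    weights; ``terminal_bias`` multiplies the weight of the designated
    terminal-enriched monomers when drawing the carboxyl-terminal root and
    the final (omega-terminal) monomer.  With ``branching_prob`` > 0 a new
    monomer may esterify a random free secondary hydroxyl instead of the
    current chain tip.
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if not 0 <= branching_prob <= 1:
        raise ValueError("branching_prob must lie in [0, 1]")
    if terminal_bias <= 0:
        raise ValueError("terminal_bias must be positive")
    rng = np.random.default_rng(seed)
    pool = [m for m in catalog.acids() if m.hydroxyls]
    if not pool:
        raise ValueError("catalog lacks hydroxyl-bearing acids to polymerize")
    base_w = _weights_for(pool, weights)

    def draw(bias_ids: tuple[str, ...] = ()) -> Monomer:
        w = base_w.copy()
        for i, m in enumerate(pool):
            if m.id in bias_ids:
                w[i] *= terminal_bias
        w = w / w.sum()
        return pool[int(rng.choice(len(pool), p=w))]

    monomers: list[Monomer] = [draw(carboxyl_terminal_ids)]
    edges: list[tuple[int, int, int]] = []
    free_sites: list[tuple[int, int]] = [
        (0, site) for site in sorted(monomers[0].hydroxyls)
    ]
    tip = 0
    for k in range(1, n_monomers):
        is_last = k == n_monomers - 1
        child = draw(omega_terminal_ids if is_last else ())
        tip_site = monomers[tip].omega_hydroxyl
        branch = (
            branching_prob > 0
            and rng.random() < branching_prob
            and any(fs != (tip, tip_site) for fs in free_sites)
        )
        if branch:
            options = sorted(fs for fs in free_sites if fs != (tip, tip_site))
            parent, site = options[int(rng.choice(len(options)))]
        else:
            parent, site = tip, tip_site
        idx = len(monomers)
        monomers.append(child)
        edges.append((idx, parent, site))
        free_sites.remove((parent, site))
        free_sites.extend((idx, s) for s in sorted(child.hydroxyls))
        if not branch:
            tip = idx
    return PolymerGraph(tuple(monomers), tuple(edges), seed=seed)


@dataclass(frozen=True)
class SimulatedDigest:
    """Fragments (with true orderings) from one stochastic partial digestion."""

    fragments: tuple[Oligomer, ...]
    n_cleaved: int
    p_cleave: float
    seed: int

    def monomer_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(mid for f in self.fragments for mid in f.ids))


def digest_polymer(
    g: PolymerGraph,
    p_cleave: float,
    max_frag_len: int | None = None,
    seed: int = 0,
    drop_oversize: bool = False,
    negative_mode_filter: bool = False,
) -> SimulatedDigest:
    """Cleave each ester bond independently with probability ``p_cleave``.

    Remaining connected subtrees are linearized to ordered oligomers
    (fragment count = cleaved edges + 1 on a tree).  Fragments longer than
    ``max_frag_len`` are dropped when ``drop_oversize`` is set, otherwise
    kept; ``negative_mode_filter`` drops fragments without a free carboxyl,
    which only matters when fatty alcohols are present.
    """
    if not 0 <= p_cleave <= 1:
        raise ValueError("p_cleave must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cleave = rng.random(len(g.edges)) < p_cleave
    kept_edges = [e for e, cut in zip(g.edges, cleave) if not cut]
    # connected components over kept edges
    component = list(range(len(g)))

    def find(x: int) -> int:
        while component[x] != x:
            component[x] = component[component[x]]
            x = component[x]
        return x

    for child, parent, _ in kept_edges:
        a, b = find(child), find(parent)
        if a != b:
            component[a] = b
    groups: dict[int, list[int]] = {}
    for node in range(len(g)):
        groups.setdefault(find(node), []).append(node)

    sub = PolymerGraph(g.monomers, tuple(kept_edges), seed=g.seed)
    fragments = []
    for root in sorted(groups):
        nodes = groups[root]
        frag = sub.fragment_oligomer(nodes)
        if max_frag_len is not None and len(frag) > max_frag_len and drop_oversize:
            continue
        if negative_mode_filter and not frag.monomers[0].carboxyls:
            continue
        fragments.append(frag)
    return SimulatedDigest(
        fragments=tuple(fragments),
        n_cleaved=int(cleave.sum()),
        p_cleave=p_cleave,
        seed=seed,
    )


def simulate_spectrum(
    o: Oligomer,
    adduct: AdductSpec | str = "[M-H]-",
    mass_error_ppm_sigma: float = 5.0,
    n_noise_peaks: int = 5,
    seed: int = 0,
    max_water_loss: int = 2,
    scan_range: tuple[float, float] = (100.0, 1700.0),
) -> Spectrum:
    """A noisy synthetic MS/MS spectrum of one oligomer.

    Theoretical ester-cleavage daughters are perturbed by Gaussian ppm mass
    error (no systematic shift); noise peaks are uniform in the scan window
    with intensity uniform in (0, median true intensity).  True peak
    intensities default to 1 -- the simulator makes no attempt at intensity
    realism because the sequencer scores presence/absence only.  The
    precursor m/z is set exactly from the oligomer.
    """
    if mass_error_ppm_sigma < 0:
        raise ValueError("mass_error_ppm_sigma must be >= 0")
    if n_noise_peaks < 0:
        raise ValueError("n_noise_peaks must be >= 0")
    rng = np.random.default_rng(seed)
    adduct = get_adduct(adduct)
    theoretical = predict_ester_fragments(o, adduct, max_water_loss=max_water_loss)
    peaks = []
    for peak in theoretical:
        shift = rng.normal(0.0, mass_error_ppm_sigma) * 1e-6 * peak.mz
        peaks.append((peak.mz + shift, 1.0))
    lo, hi = scan_range
    for _ in range(n_noise_peaks):
        peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(0.0, 1.0))))
    return Spectrum(
        precursor_mz=precursor_mz(o, adduct),
        adduct=adduct,
        peaks=tuple(peaks),
        source_id=f"sim-seed{seed}",
    )
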