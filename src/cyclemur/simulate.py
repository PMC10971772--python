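"""Synthetic storm tracks, range polygons, phylogenies, and trait vectors.

Everything downstream of raw data — the impact grid, the resilience score,
Moran's I and the joint phylogenetic-spatial GLS — can be exercised on
synthetic inputs drawn from the same statistical structure the analysis
assumes:

* storm tracks are random-walk polylines (fixed 50 km steps, Gaussian
  turning angles) whose points carry Saffir classes drawn from a
  configurable distribution and winds drawn inside the class band;
* species ranges are buffered random ellipses clipped to the study box;
* phylogenies are ultrametric Yule (pure-birth) trees;
* traits are drawn from the exact generative counterpart of the GLS:
  y ~ MVN(X beta, sigma2 * R(lambda_p, phi_s, delta)).

A single seed is split into per-generator substreams (tracks, ranges,
tree, traits — in that order) so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from shapely import affinity
from shapely.geometry import Point, Polygon, box

from .errors import AlignmentError, ConfigError
from .gls import CorrelationModel, joint_correlation, phylo_correlation, spatial_structure
from .impact import SpeciesRange, StormTrack

#: wind bands (knots) per Saffir class; class 0 is tropical-storm strength
SAFFIR_WIND_BANDS_KT: dict[int, tuple[float, float]] = {
    0: (34.0, 63.0),
    1: (64.0, 82.0),
    2: (83.0, 95.0),
    3: (96.0, 112.0),
    4: (113.0, 136.0),
    5: (137.0, 160.0),
}

TRACK_STEP_KM = 50.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic inputs.

    The trait-model block (beta, sigma2, lambda_p, phi_s, delta) mirrors
    the GLS parameterisation exactly, so simulated traits can be used for
    parameter-recovery and calibration experiments.
    """

    n_storms: int = 50
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 500.0, 1000.0)
    saffir_probs: tuple[float, ...] = (0.45, 0.2, 0.13, 0.1, 0.07, 0.05)
    n_species: int = 26
    birth_rate: float = 1.0
    beta: tuple[float, ...] = (0.0,)
    sigma2: float = 1.0
    lambda_p: float = 0.0
    phi_s: float = 0.0
    delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_storms < 0 or self.n_species < 0:
            raise ConfigError("counts must be non-negative")
        x0, y0, x1, y1 = self.bbox
        if x1 <= x0 or y1 <= y0:
            raise ConfigError(f"degenerate bbox {self.bbox}")
        p = np.asarray(self.saffir_probs, dtype=float)
        if len(p) != 6 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("saffir_probs must be 6 non-negative values summing to 1")
        if not (0 <= self.lambda_p < 1 and 0 <= self.phi_s < 1):
            raise ConfigError("lambda_p and phi_s must lie in [0, 1)")
        if self.lambda_p + self.phi_s > 1:
            raise ConfigError("lambda_p + phi_s must not exceed 1")
        if not 0 <= self.delta < 1:
            raise ConfigError("delta must lie in [0, 1)")
        if self.sigma2 <= 0:
            raise ConfigError("sigma2 must be positive")

    def substreams(self) -> dict[str, np.random.Generator]:
        """Named per-generator RNG substreams in a fixed, documented order."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("tracks", "ranges", "tree", "traits")
        return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


def gen_tracks(cfg: SimConfig) -> list[StormTrack]:
    """Random-walk storm tracks with per-point Saffir class and wind.

    Tracks start inside a bbox expanded by 500 km on every side (so some
    storms pass offshore and exercise the distance filter), take 50 km
    steps with Gaussian turning-angle increments (sd 25 degrees), and run
    for 10-60 points.
    """
    rng = cfg.substreams()["tracks"]
    x0, y0, x1, y1 = cfg.bbox
    pad = 500.0
    probs = np.asarray(cfg.saffir_probs, dtype=float)
    tracks = []
    for s in range(cfg.n_storms):
        n_pts = int(rng.integers(10, 61))
        start = rng.uniform([x0 - pad, y0 - pad], [x1 + pad, y1 + pad])
        heading = rng.uniform(0, 2 * np.pi)
        pts = np.empty((n_pts, 2))
        pts[0] = start
        for i in range(1, n_pts):
            heading += rng.normal(0.0, np.deg2rad(25.0))
            pts[i] = pts[i - 1] + TRACK_STEP_KM * np.array(
                [np.cos(heading), np.sin(heading)]
            )
        saffir = rng.choice(6, size=n_pts, p=probs)
        lo = np.array([SAFFIR_WIND_BANDS_KT[c][0] for c in saffir])
        hi = np.array([SAFFIR_WIND_BANDS_KT[c][1] for c in saffir])
        wind = rng.uniform(lo, hi)
        tracks.append(StormTrack(f"SYN{s:04d}", pts, wind, saffir))
    return tracks


def gen_ranges(cfg: SimConfig) -> list[SpeciesRange]:
    """Species ranges as buffered random ellipses clipped to the bbox.

    Always-valid simple polygons; ranges may overlap, as real congeneric
    ranges do.  Species ids are s001..sNNN.
    """
    if cfg.n_species < 1:
        raise ConfigError("n_species must be at least 1")
    rng = cfg.substreams()["ranges"]
    x0, y0, x1, y1 = cfg.bbox
    w, h = x1 - x0, y1 - y0
    bbox_poly = box(x0, y0, x1, y1)
    scale = min(w, h)
    out = []
    for i in range(cfg.n_species):
        cx = rng.uniform(x0 + 0.1 * w, x1 - 0.1 * w)
        cy = rng.uniform(y0 + 0.1 * h, y1 - 0.1 * h)
        a = rng.uniform(0.05, 0.25) * scale  # semi-axes, km
        b = rng.uniform(0.05, 0.25) * scale
        angle = rng.uniform(0, 180.0)
        circ = Point(cx, cy).buffer(1.0, quad_segs=16)
        ell = affinity.rotate(affinity.scale(circ, a, b), angle, origin=(cx, cy))
        poly = ell.intersection(bbox_poly)
        if poly.is_empty or poly.geom_type != "Polygon":
            poly = ell.buffer(0).intersection(bbox_poly)
        out.append(SpeciesRange(species_id=f"s{i + 1:03d}", polygon=poly))
    return out


def gen_tree(cfg: SimConfig) -> dendropy.Tree:
    """Ultrametric binary Yule tree with tip labels matching gen_ranges ids.

    Forward pure-birth simulation: starting from the root split (two
    lineages at time 0), every extant lineage splits at rate ``birth_rate``,
    so with k lineages the waiting time to the next split is
    Exp(k * birth_rate).  The simulation stops once n lineages exist, then
    runs one further Exp(n * birth_rate) waiting time to place the present,
    giving proper pendant branch lengths.  The expected lineage count at
    depth t is 2 * exp(birth_rate * t) under this construction.
    """
    if cfg.n_species < 2:
        raise ConfigError("n_species must be at least 2 for a tree")
    if cfg.birth_rate <= 0:
        raise ConfigError("birth_rate must be positive")
    rng = cfg.substreams()["tree"]
    n = cfg.n_species
    taxa = dendropy.TaxonNamespace([f"s{i + 1:03d}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)

    root = dendropy.Node()
    # active lineages: (node, time its edge started)
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (cfg.birth_rate * k))
        idx = int(rng.integers(k))
        node, t_start = active.pop(idx)
        node.edge.length = t - t_start
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_present = t + rng.exponential(1.0 / (cfg.birth_rate * n))
    order = rng.permutation(n)
    for (node, t_start), tax_i in zip(active, order):
        node.edge.length = t_present - t_start
        node.taxon = taxa[int(tax_i)]
    root.edge.length = 0.0
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def gen_traits(
    tree: dendropy.Tree,
    ranges: list[SpeciesRange],
    design: np.ndarray,
    cfg: SimConfig,
    *,
    n_reps: int = 1,
) -> np.ndarray:
    """Traits from the GLS generative model: y ~ MVN(X beta, sigma2 R).

    R blends the tree's phylogenetic correlation with a distance-decay
    spatial correlation on range centroids, using (lambda_p, phi_s, delta)
    from the config.  Draws use a symmetric eigendecomposition square root
    of R with a tiny diagonal jitter guarding semi-definite cases.

    Returns shape (n,) for one replicate or (n_reps, n) otherwise.
    """
    labels = [r.species_id for r in ranges]
    tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if set(labels) != tree_tips:
        raise AlignmentError(
            f"range ids and tree tips differ: {sorted(set(labels) ^ tree_tips)}"
        )
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != len(labels):
        raise AlignmentError("design rows do not match the number of species")
    beta = np.asarray(cfg.beta, dtype=float)
    if len(beta) != X.shape[1]:
        raise AlignmentError(
            f"beta has {len(beta)} entries for {X.shape[1]} design columns"
        )

    P, _ = phylo_correlation(tree, labels)
    D = spatial_structure(np.array([r.centroid for r in ranges]))
    model = CorrelationModel(cfg.lambda_p, cfg.phi_s, cfg.delta)
    R = joint_correlation(P, D, model)
    n = len(labels)
    vals, vecs = np.linalg.eigh(R + 1e-10 * np.eye(n))
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T

    rng = cfg.substreams()["traits"]
    mean = X @ beta
    z = rng.standard_normal((n_reps, n))
    y = mean + np.sqrt(cfg.sigma2) * z @ root.T
    return y[0] if n_reps == 1 else y
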