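"""Seeded generators of synthetic landmark data with known ground truth.

The generator emulates the design of a comparative skull-shape study:
species mean shapes evolve by multivariate Brownian motion (BM) on a
pure-birth tree; optional habitat effects displace means along a fixed
direction and focal tip pairs can be pulled toward their mutual midpoint to
force convergence; specimens are species means plus bilaterally symmetric
and asymmetric digitizing noise, optional replicate measurements, and
randomly missing landmarks.

The default template is a bilaterally symmetric 17-landmark skull-like
configuration (6 bilateral pairs + 5 midline points) at a realistic
neurocranium scale (~60 mm long), and the default study dimensions follow
the emulated design: 28 species, ~9 specimens per species, measurement
noise well below among-species shape differences.

Species means are kept exactly bilaterally symmetric: BM increments and the
habitat-effect direction are drawn in the symmetric subspace of the
symmetry map (paired landmarks receive mirrored increments; midline
landmarks receive no increment along the reflection axis).  Real shape data
are analysed through their symmetric component anyway, and this choice
makes the symmetric/asymmetric decomposition of simulated specimens exact.
A consequence is that midline landmarks have zero mean-shape variance along
the reflection axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LandmarkConfiguration, SymmetryMap
from .phylo import Phylogeny, normalize_label

__all__ = [
    "SimulationSpec",
    "default_template",
    "default_symmetry_map",
    "simulate_tree",
    "simulate_species_means",
    "make_specimens",
    "simulate_dataset",
    "assign_genera",
]

HABITATS = ("marine", "brackish", "fresh")

# bilateral pairing of the 17-landmark scheme (0-based): five pairs follow the
# emulated digitizing scheme (posterior skull corners, sphenotic-frontal,
# ethmoid tips, mesethmoid margins, supraoccipital process outline) plus one
# additional lateral pair; remaining five points sit on the midline
_DEFAULT_PAIRS = ((0, 9), (1, 8), (2, 7), (3, 6), (10, 13), (11, 12))
_DEFAULT_MIDLINE = (4, 5, 14, 15, 16)


def default_symmetry_map() -> SymmetryMap:
    return SymmetryMap(paired=_DEFAULT_PAIRS, midline=_DEFAULT_MIDLINE)


def default_template() -> np.ndarray:
    """Bilaterally symmetric 17-landmark skull-like template (mm).

    y runs anterior (+) to posterior (-), x is the left-right axis (the
    reflection plane is x = 0), z is dorsoventral.  Left-side landmarks have
    x > 0 and their right partners are exact mirror images.
    """
    t = np.zeros((17, 3))
    # pairs (left, right): posterior corners, braincase waist, ethmoid tips,
    # mesethmoid margins, supraoccipital outline, lateral braincase wall
    left = {
        0: (14.0, -30.0, 2.0),   # posterior-most corner
        1: (9.0, -8.0, 6.0),     # sphenotic/frontal meeting point
        2: (7.0, 24.0, 3.0),     # distal ethmoid
        3: (3.5, 30.0, 2.5),     # mesethmoid margin
        10: (5.0, -22.0, 9.0),   # supraoccipital process outline
        11: (11.0, -18.0, 4.0),  # lateral braincase wall
    }
    for (l_idx, r_idx), xyz in zip(_DEFAULT_PAIRS, left.values()):
        t[l_idx] = xyz
        t[r_idx] = (-xyz[0], xyz[1], xyz[2])
    # midline: anterior mesethmoid tip, vomer, mid-frontal, supraoccipital
    # crest apex, posterior braincase floor
    t[4] = (0.0, 33.0, 1.5)
    t[5] = (0.0, 18.0, -2.0)
    t[14] = (0.0, -2.0, 8.0)
    t[15] = (0.0, -20.0, 12.0)
    t[16] = (0.0, -28.0, -3.0)
    return t


@dataclass
class SimulationSpec:
    """Ground-truth parameters of one simulated study.

    Defaults mirror the emulated study design: 28 species on a unit-depth
    tree, 9 specimens per species, replicate measurement error at digitizer
    accuracy (0.38 mm), sparse missing landmarks.
    """

    n_tips: int = 28
    base_shape: np.ndarray = field(default_factory=default_template)
    symmetry_map: SymmetryMap = field(default_factory=default_symmetry_map)
    bm_rate: float = 2.0  # mm^2 per unit tree depth, per free coordinate
    habitat_assignment: dict[str, str] | None = None
    habitat_effect: float = 0.0  # mm, along a fixed symmetric unit direction
    convergent_pairs: tuple[tuple[str, str, float], ...] = ()
    n_specimens_per_species: int = 9
    symmetric_noise_sd: float = 0.5  # mm
    asymmetric_noise_sd: float = 0.25  # mm
    replicate_error_sd: float = 0.38  # mm, digitizer accuracy
    n_replicated_specimens: int = 0
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        for name in ("bm_rate", "symmetric_noise_sd", "asymmetric_noise_sd",
                     "replicate_error_sd", "habitat_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for a, b, w in self.convergent_pairs:
            if not 0 <= w <= 1:
                raise ValueError(f"convergence weight for ({a}, {b}) outside [0, 1]")
        self.base_shape = np.asarray(self.base_shape, dtype=float)
        self.symmetry_map.validate_for(self.base_shape.shape[0])
        if not np.allclose(self.base_shape, _reflect(self.base_shape, self.symmetry_map)):
            raise ValueError("base_shape must be exactly symmetric under the symmetry map")

    @property
    def n_landmarks(self) -> int:
        return self.base_shape.shape[0]


def _reflect(shape: np.ndarray, smap: SymmetryMap) -> np.ndarray:
    from .geometry import reflect_relabel

    return reflect_relabel(shape, smap)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


class _YuleNode:
    __slots__ = ("birth", "split", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.split: float | None = None
        self.children: list["_YuleNode"] = []
        self.label = ""


def simulate_tree(spec: SimulationSpec, rng: np.random.Generator | None = None) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips, scaled to unit depth.

    Lineages split at exponential waiting times (unit birth rate, one
    uniformly chosen lineage per event); after the last split all lineages
    are extended by one final exponential waiting time, giving an
    ultrametric tree whose tip depths are then rescaled to exactly 1.
    """
    rng = _rng(spec.seed if rng is None else rng)
    n = spec.n_tips
    root = _YuleNode(0.0)
    root.split = 0.0
    root.children = [_YuleNode(0.0), _YuleNode(0.0)]
    active = list(root.children)
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.split = t
        node.children = [_YuleNode(t), _YuleNode(t)]
        active.extend(node.children)
    t_end = t + rng.exponential(1.0 / n)

    counter = 0

    def to_newick(node: _YuleNode) -> str:
        nonlocal counter
        if not node.children:
            counter += 1
            node.label = f"sp{counter:02d}"
            return f"{node.label}:{float((t_end - node.birth) / t_end):.17g}"
        inner = ",".join(to_newick(ch) for ch in node.children)
        if node is root:
            return f"({inner})"
        return f"({inner}):{float((node.split - node.birth) / t_end):.17g}"

    return Phylogeny.from_newick(to_newick(root) + ";")


def simulate_species_means(
    spec: SimulationSpec, tree: Phylogeny, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Species mean shapes: symmetric-subspace BM plus habitat and convergence effects.

    Returns a DataFrame (rows = tree tips in tree order, columns = flattened
    coordinates).  Habitat offsets are applied along one fixed unit direction
    drawn in the symmetric subspace and orthogonalized against the template,
    scaled by ``habitat_effect`` times a per-habitat multiplier (marine +1,
    brackish 0, fresh -1).  Each convergent pair's tips are then pulled
    toward their mutual midpoint by the pair's weight (weight 1 makes them
    identical).
    """
    rng = _rng(spec.seed + 1 if rng is None else rng)
    k = spec.n_landmarks
    smap = spec.symmetry_map
    n_nodes = len(tree.nodes)
    states = np.zeros((n_nodes, k, 3))
    states[0] = spec.base_shape
    for parent, child, length in tree.edges():
        states[child] = states[parent] + _symmetric_increment(
            rng, k, smap, np.sqrt(spec.bm_rate * length)
        )
    tip_idx = [tree.node_for_tip(lab).index for lab in tree.tip_labels]
    means = states[tip_idx].reshape(tree.n_tips, -1)

    labels = tree.tip_labels
    if spec.habitat_effect > 0:
        habitats = habitat_of(spec, labels)
        direction = habitat_direction(spec)
        mult = {"marine": 1.0, "brackish": 0.0, "fresh": -1.0}
        for i, lab in enumerate(labels):
            means[i] += spec.habitat_effect * mult[habitats[lab]] * direction

    pos = {lab: i for i, lab in enumerate(labels)}
    for a, b, w in spec.convergent_pairs:
        ia, ib = pos[normalize_label(a)], pos[normalize_label(b)]
        mid = 0.5 * (means[ia] + means[ib])
        means[ia] = (1 - w) * means[ia] + w * mid
        means[ib] = (1 - w) * means[ib] + w * mid

    return pd.DataFrame(means, index=pd.Index(labels, name="species"))


def _symmetric_increment(
    rng: np.random.Generator, k: int, smap: SymmetryMap, sd: float
) -> np.ndarray:
    """Draw a K x 3 perturbation in the bilaterally symmetric subspace.

    Paired landmarks get mirrored perturbations; midline landmarks get none
    along the reflection (first) axis.  Every unconstrained coordinate has
    standard deviation ``sd``.
    """
    out = np.zeros((k, 3))
    if sd == 0:
        return out
    for l_idx, r_idx in smap.paired:
        d = rng.normal(0.0, sd, 3)
        out[l_idx] = d
        out[r_idx] = (-d[0], d[1], d[2])
    for m in smap.midline:
        out[m, 1:] = rng.normal(0.0, sd, 2)
    return out


def _antisymmetric_increment(
    rng: np.random.Generator, k: int, smap: SymmetryMap, sd: float
) -> np.ndarray:
    """Perturbation in the orthogonal complement of the symmetric subspace."""
    out = np.zeros((k, 3))
    if sd == 0:
        return out
    for l_idx, r_idx in smap.paired:
        d = rng.normal(0.0, sd, 3)
        out[l_idx] = d
        out[r_idx] = (d[0], -d[1], -d[2])
    for m in smap.midline:
        out[m, 0] = rng.normal(0.0, sd)
    return out


def habitat_of(spec: SimulationSpec, labels: list[str]) -> dict[str, str]:
    """Resolve the habitat of every tip: user map or a seeded uniform draw."""
    if spec.habitat_assignment is not None:
        out = {normalize_label(k): v for k, v in spec.habitat_assignment.items()}
        missing = [lab for lab in labels if lab not in out]
        if missing:
            raise ValueError(f"habitat_assignment lacks tips {missing}")
        bad = sorted({v for v in out.values()} - set(HABITATS))
        if bad:
            raise ValueError(f"unknown habitats {bad}; allowed: {HABITATS}")
        return out
    rng = np.random.default_rng(spec.seed + 2)
    return {lab: HABITATS[int(rng.integers(3))] for lab in labels}


def habitat_direction(spec: SimulationSpec) -> np.ndarray:
    """Fixed unit direction of the habitat effect (flattened, symmetric subspace),
    orthogonalized against the flattened template."""
    rng = np.random.default_rng(spec.seed + 3)
    raw = _symmetric_increment(rng, spec.n_landmarks, spec.symmetry_map, 1.0).ravel()
    base = spec.base_shape.ravel()
    raw = raw - (raw @ base) / (base @ base) * base
    return raw / np.linalg.norm(raw)


def assign_genera(tree: Phylogeny, cut_depth: float = 0.5) -> dict[str, str]:
    """Group tips into synthetic 'genera': the maximal clades whose stem edge
    crosses ``cut_depth`` (fraction of tree depth)."""
    depth = tree.depths.max()
    cut = cut_depth * depth
    genera: dict[str, str] = {}
    counter = 0
    for node in tree.nodes:
        parent = node.parent_node
        if parent is None:
            continue
        if tree.depths[parent.index] < cut <= tree.depths[node.index]:
            counter += 1
            name = f"gen{counter:02d}"
            members = (
                [node.taxon.label]
                if node.is_leaf()
                else [lf.taxon.label for lf in node.leaf_iter()]
            )
            for lab in members:
                genera[lab] = name
    return genera


def make_specimens(
    spec: SimulationSpec,
    species_means: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[list[LandmarkConfiguration], pd.DataFrame]:
    """Specimen-level landmark configurations plus a metadata table.

    Each specimen is its species mean plus symmetric noise (mirrored across
    the symmetry map) and asymmetric noise (anti-mirrored), measured once —
    or twice for the first ``n_replicated_specimens`` specimens — with
    independent replicate (digitizing) error per measurement, and landmarks
    masked independently at ``missing_rate`` (never below 4 present).
    """
    rng = _rng(spec.seed + 4 if rng is None else rng)
    k = spec.n_landmarks
    smap = spec.symmetry_map
    configs: list[LandmarkConfiguration] = []
    meta_rows = []
    n_replicated = 0
    for species in species_means.index:
        mean = species_means.loc[species].to_numpy().reshape(k, 3)
        for j in range(spec.n_specimens_per_species):
            true_config = (
                mean
                + _symmetric_increment(rng, k, smap, spec.symmetric_noise_sd)
                + _antisymmetric_increment(rng, k, smap, spec.asymmetric_noise_sd)
            )
            individual = f"{species}_i{j + 1}"
            n_meas = 2 if n_replicated < spec.n_replicated_specimens else 1
            n_replicated += 1 if n_meas == 2 else 0
            for rep in range(1, n_meas + 1):
                coords = true_config + rng.normal(0.0, spec.replicate_error_sd, (k, 3))
                mask = rng.random(k) >= spec.missing_rate
                while mask.sum() < 4:
                    mask[int(rng.integers(k))] = True
                spec_id = individual if n_meas == 1 else f"{individual}_r{rep}"
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=spec_id, coords=coords, present_mask=mask
                    )
                )
                meta_rows.append(
                    {
                        "specimen_id": spec_id,
                        "individual_id": individual,
                        "species": species,
                        "replicate_id": rep if n_meas == 2 else "",
                    }
                )
    meta = pd.DataFrame(meta_rows)
    return configs, meta


def simulate_dataset(spec: SimulationSpec):
    """Full synthetic study bundle: tree, species means, specimens, metadata.

    Metadata gains habitat and genus columns.  All randomness derives from
    ``spec.seed`` through fixed per-stage substreams, so the bundle is fully
    reproducible.
    """
    tree = simulate_tree(spec)
    means = simulate_species_means(spec, tree)
    configs, meta = make_specimens(spec, means)
    habitats = habitat_of(spec, tree.tip_labels)
    genera = assign_genera(tree)
    meta["habitat"] = meta["species"].map(habitats)
    meta["genus"] = meta["species"].map(lambda s: genera.get(s, "gen00"))
    return tree, means, configs, meta
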