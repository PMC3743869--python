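"""Synthetic branching colonies and diploid intron-marker genotypes.

Every downstream stage of the package (morphometrics, genetic distances,
tree building, congruence testing) is exercised on data from this module, so
each generator records its ground truth:

* ``generate_colony_blueprint`` builds a recursive binary branching
  structure in mm coordinates and records exact per-segment radii, lengths,
  inter-child branching angles and growth angles, plus tip-to-nearest-branch
  spacing — the quantities the morphometric stage must recover.
* ``rasterize`` turns a blueprint into an anisotropic voxel volume the way a
  CT scan would sample it.
* ``simulate_genotypes`` evolves two alleles per sample down a star species
  tree under a Jukes–Cantor model, with heterozygotes, homozygotes and
  optional hybrid samples whose two alleles descend from different species
  lineages (the pattern seen in natural interspecific hybrids).
* ``generate_congruent_dataset`` couples a morphological feature matrix to a
  genetic distance matrix with tunable effect size, for power and type-I
  error studies of the congruence tests.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import dendropy

from .matrices import DistanceMatrix, FeatureMatrix

__all__ = [
    "ColonySegment",
    "ColonyBlueprint",
    "SimulatedGenotypeSet",
    "generate_colony_blueprint",
    "rasterize",
    "simulate_genotypes",
    "generate_congruent_dataset",
    "jc_expected_p_distance",
    "default_species_params",
]


# ----------------------------------------------------------------------
# Colony geometry
# ----------------------------------------------------------------------

@dataclass
class ColonySegment:
    """One straight branch segment between consecutive junctions."""

    start: np.ndarray  # mm
    end: np.ndarray  # mm
    radius: float  # mm
    parent: int | None  # index of parent segment, None for the basal one
    generation: int

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)


@dataclass
class ColonyBlueprint:
    """Ground-truth description of a synthetic branching colony.

    ``true_b_angles`` maps parent segment index -> inter-child angle in
    degrees at that bifurcation.  ``growth_axis`` follows the +y convention
    used for growth-direction angles.
    """

    species_label: str
    segments: list[ColonySegment]
    growth_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    true_b_angles: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("blueprint has no segments")
        for i, seg in enumerate(self.segments):
            if seg.radius <= 0:
                raise ValueError(f"segment {i} has nonpositive radius")
            if seg.parent is not None:
                if not np.allclose(seg.start, self.segments[seg.parent].end, atol=1e-9):
                    raise ValueError(f"segment {i} does not start on its parent's end")

    # ---------------- derived ground truth ----------------
    @property
    def n_bifurcations(self) -> int:
        counts: dict[int, int] = {}
        for seg in self.segments:
            if seg.parent is not None:
                counts[seg.parent] = counts.get(seg.parent, 0) + 1
        return sum(1 for v in counts.values() if v >= 2)

    def children_of(self, i: int) -> list[int]:
        return [j for j, s in enumerate(self.segments) if s.parent == i]

    def tip_segments(self) -> list[int]:
        has_child = {s.parent for s in self.segments if s.parent is not None}
        return [i for i in range(len(self.segments)) if i not in has_child]

    def true_g_angle(self, i: int) -> float:
        """Angle (degrees) between segment direction and the growth axis."""
        c = float(np.clip(self.segments[i].direction @ self.growth_axis, -1, 1))
        return math.degrees(math.acos(c))

    def mean_radius(self) -> float:
        return float(np.mean([s.radius for s in self.segments]))

    def true_tip_spacing(self, i: int) -> float:
        """Distance from tip of segment i to the nearest other segment's centerline."""
        tip = self.segments[i].end
        best = math.inf
        for j, seg in enumerate(self.segments):
            if j == i or seg.parent == i or self.segments[i].parent == j:
                continue  # skip self and touching neighbours
            best = min(best, _point_segment_distance(tip, seg.start, seg.end))
        return best

    def bounding_box(self, margin: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        pts = np.array([p for s in self.segments for p in (s.start, s.end)])
        radii = max(s.radius for s in self.segments)
        return pts.min(axis=0) - radii - margin, pts.max(axis=0) + radii + margin


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = float(np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _segment_segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 3D line segments."""
    u, v, w = a1 - a0, b1 - b0, a0 - b0
    A, B, C = u @ u, u @ v, v @ v
    D, E = u @ w, v @ w
    den = A * C - B * B
    if den > 1e-12:
        s = np.clip((B * E - C * D) / den, 0.0, 1.0)
    else:
        s = 0.0
    t = (B * s + E) / C if C > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # refine s for the clamped t
    s = np.clip((B * t - D) / A, 0.0, 1.0) if A > 1e-12 else 0.0
    return float(np.linalg.norm((a0 + s * u) - (b0 + t * v)))


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle_rad)
        + np.cross(axis, v) * math.sin(angle_rad)
        + axis * (axis @ v) * (1 - math.cos(angle_rad))
    )


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        w = r - (r @ v) * v
        n = np.linalg.norm(w)
        if n > 1e-8:
            return w / n


def generate_colony_blueprint(
    species_params: dict,
    seed: int,
    *,
    species_label: str = "colony",
    max_overlap_fraction: float = 0.25,
) -> ColonyBlueprint:
    """Grow a recursive binary branching colony with known ground truth.

    Parameters
    ----------
    species_params
        Keys: ``mean_radius`` (mm), ``mean_branch_length`` (mm),
        ``branch_angle`` (degrees, inter-child angle at a bifurcation),
        ``n_generations`` (>= 1), optional ``spacing_target`` (mm; overrides
        branch_angle so sibling tips end up roughly this far apart),
        optional ``angle_jitter`` (degrees s.d., default 5),
        optional ``length_jitter`` (relative s.d., default 0.1),
        optional ``radius_taper`` (per-generation factor, default 0.9).
    seed
        Seed for all randomness; identical (params, seed) -> identical blueprint.
    max_overlap_fraction
        Reject geometries in which more than this fraction of segments come
        closer than the sum of radii to a non-adjacent segment.
    """
    p = dict(species_params)
    mean_radius = float(p["mean_radius"])
    mean_len = float(p["mean_branch_length"])
    n_gen = int(p["n_generations"])
    branch_angle = float(p.get("branch_angle", 40.0))
    spacing_target = p.get("spacing_target")
    angle_jitter = float(p.get("angle_jitter", 5.0))
    length_jitter = float(p.get("length_jitter", 0.1))
    taper = float(p.get("radius_taper", 0.9))
    if mean_radius <= 0 or mean_len <= 0 or branch_angle <= 0:
        raise ValueError("species_params must be positive")
    if n_gen < 1:
        raise ValueError("n_generations must be >= 1")

    rng = np.random.default_rng(seed)
    growth = np.array([0.0, 1.0, 0.0])

    segments: list[ColonySegment] = []
    b_angles: dict[int, float] = {}

    def seg_length(gen: int) -> float:
        return max(0.2 * mean_len, mean_len * (1 + length_jitter * rng.standard_normal()))

    root_len = seg_length(0)
    segments.append(
        ColonySegment(np.zeros(3), growth * root_len, mean_radius, None, 0)
    )

    frontier = [0]
    for gen in range(1, n_gen):
        nxt = []
        radius = mean_radius * taper**gen
        for parent in frontier:
            pseg = segments[parent]
            child_len = seg_length(gen)
            if spacing_target is not None:
                half = math.degrees(
                    math.asin(min(0.99, float(spacing_target) / (2.0 * child_len)))
                )
            else:
                half = branch_angle / 2.0
            jit = angle_jitter * rng.standard_normal(2)
            w = _perpendicular(pseg.direction, rng)
            axis = _axis_for(pseg.direction, w)
            dirs = []
            for sign, j in ((+1, jit[0]), (-1, jit[1])):
                ang = math.radians(sign * (half + j))
                dirs.append(_rotate_about(pseg.direction, axis, ang))
            # record the realized inter-child angle
            cosang = float(np.clip(dirs[0] @ dirs[1], -1, 1))
            b_angles[parent] = math.degrees(math.acos(cosang))
            for d in dirs:
                d = d / np.linalg.norm(d)
                seg = ColonySegment(pseg.end.copy(), pseg.end + d * child_len, radius, parent, gen)
                segments.append(seg)
                nxt.append(len(segments) - 1)
        frontier = nxt

    bp = ColonyBlueprint(species_label, segments, growth, b_angles)

    # degenerate-geometry guard: non-adjacent segments overlapping
    n_bad = 0
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            si, sj = segments[i], segments[j]
            if si.parent == j or sj.parent == i or si.parent == sj.parent:
                continue
            d = _segment_segment_distance(si.start, si.end, sj.start, sj.end)
            if d < si.radius + sj.radius:
                n_bad += 1
    if n_bad / max(1, len(segments)) > max_overlap_fraction:
        raise ValueError(
            f"degenerate geometry: {n_bad} non-adjacent segment overlaps for "
            f"{len(segments)} segments exceeds overlap fraction {max_overlap_fraction}"
        )
    return bp


def _axis_for(direction: np.ndarray, perp: np.ndarray) -> np.ndarray:
    """Rotation axis so children fan out symmetrically within one plane."""
    ax = np.cross(direction, perp)
    return ax / np.linalg.norm(ax)


def rasterize(
    blueprint: ColonyBlueprint,
    spacing: tuple[float, float, float],
    *,
    pad_voxels: int = 3,
    crop_box: tuple[np.ndarray, np.ndarray] | None = None,
) -> "VoxelVolume":
    """Sample a blueprint onto an anisotropic voxel grid.

    A voxel is foreground iff its center lies within ``radius`` of any
    segment's centerline (capsule geometry, computed in mm).  The volume is
    padded by at least ``pad_voxels`` background voxels on every face.
    """
    from .volume import VoxelVolume

    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    if not blueprint.segments:
        raise ValueError("empty blueprint")
    lo, hi = blueprint.bounding_box()
    if crop_box is not None:
        clo, chi = np.asarray(crop_box[0], float), np.asarray(crop_box[1], float)
        if np.any(hi < clo) or np.any(lo > chi):
            raise ValueError("blueprint lies entirely outside the requested crop box")
        lo, hi = np.maximum(lo, clo), np.minimum(hi, chi)
    sp = np.asarray(spacing)
    origin = lo - pad_voxels * sp
    shape = np.ceil((hi - origin) / sp).astype(int) + pad_voxels + 1
    occ = np.zeros(tuple(shape), dtype=bool)

    ax_x = origin[0] + np.arange(shape[0]) * sp[0]
    ax_y = origin[1] + np.arange(shape[1]) * sp[1]
    ax_z = origin[2] + np.arange(shape[2]) * sp[2]

    for seg in blueprint.segments:
        a, b, r = seg.start, seg.end, seg.radius
        slo = np.minimum(a, b) - r - sp
        shi = np.maximum(a, b) + r + sp
        i0 = np.maximum(np.floor((slo - origin) / sp).astype(int), 0)
        i1 = np.minimum(np.ceil((shi - origin) / sp).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        X, Y, Z = np.meshgrid(
            ax_x[i0[0]:i1[0]], ax_y[i0[1]:i1[1]], ax_z[i0[2]:i1[2]], indexing="ij"
        )
        P = np.stack([X, Y, Z], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((P - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(P.shape[:-1])
        closest = a + t[..., None] * ab
        d2 = np.sum((P - closest) ** 2, axis=-1)
        occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r

    return VoxelVolume(occ, spacing, tuple(origin))


# ----------------------------------------------------------------------
# Sequence simulation
# ----------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def jc_expected_p_distance(d_subs: float) -> float:
    """Expected p-distance after ``d_subs`` substitutions/site under Jukes–Cantor."""
    return 0.75 * (1.0 - math.exp(-4.0 * d_subs / 3.0))


def _evolve(seq: np.ndarray, branch_len: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence along a branch of given expected substitutions/site.

    Site-i.i.d. equal-rates model: each site changes to one of the three
    other bases with total probability 3/4*(1 - exp(-4/3 b)).
    """
    p_change = jc_expected_p_distance(branch_len)
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    if hit.any():
        idx = np.flatnonzero(hit)
        cur = np.searchsorted(_BASES, seq[idx])
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = _BASES[(cur + shift) % 4]
    return out


@dataclass
class SimulatedGenotypeSet:
    """Diploid samples with 1 (homozygote) or 2 (heterozygote) alleles."""

    samples: list[tuple[str, str, str, str | None]]  # (sample_id, species, allele1, allele2-or-None)
    true_tree: dendropy.Tree
    params: dict

    def allele_fastas(self) -> list[tuple[str, str]]:
        """(id, sequence) pairs using the "<Sample>-1"/"<Sample>-2" suffix convention."""
        out = []
        for sid, _sp, a1, a2 in self.samples:
            if a2 is None:
                out.append((sid, a1))
            else:
                out.append((f"{sid}-1", a1))
                out.append((f"{sid}-2", a2))
        return out

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.allele_fastas():
                fh.write(f">{name}\n{seq}\n")

    def species_of(self) -> dict[str, str]:
        return {sid: sp for sid, sp, _a, _b in self.samples}


def simulate_genotypes(
    n_per_species: int,
    n_species: int,
    seq_length: int,
    divergence: float,
    heterozygosity: float,
    hybrid_samples: int = 0,
    seed: int = 0,
    *,
    within_depth_fraction: float = 0.05,
    species_names: list[str] | None = None,
) -> SimulatedGenotypeSet:
    """Simulate two-allele nuclear-intron genotypes for several species.

    The species tree is a star: all species split at a common root so the
    expected number of substitutions/site between alleles of different
    species equals ``divergence`` (closed-form expected p-distance:
    3/4*(1-exp(-4/3*divergence))).  Within a species, allele lineages
    coalesce at ``within_depth_fraction * divergence`` below the species
    ancestor.  Heterozygotes carry two distinct allele draws; homozygotes
    store a single allele.  Each hybrid sample receives allele 1 from its
    nominal species and allele 2 from a different species' lineage.
    """
    if seq_length < 50:
        raise ValueError("seq_length must be >= 50")
    if not 0 <= heterozygosity <= 1:
        raise ValueError("heterozygosity must be in [0,1]")
    if hybrid_samples > 0 and n_species < 2:
        raise ValueError("hybrid samples require at least 2 species")
    rng = np.random.default_rng(seed)

    if species_names is None:
        species_names = [f"SP{k + 1}" for k in range(n_species)]
    half = divergence / 2.0  # root-to-species-ancestor depth (subs/site)
    within = within_depth_fraction * divergence

    root_seq = _BASES[rng.integers(0, 4, size=seq_length)]
    species_anc = {
        sp: _evolve(root_seq, max(0.0, half - within), rng) for sp in species_names
    }

    def draw_allele(sp: str) -> np.ndarray:
        return _evolve(species_anc[sp], within, rng)

    samples: list[tuple[str, str, str, str | None]] = []
    hybrid_left = hybrid_samples
    for k, sp in enumerate(species_names):
        for i in range(n_per_species):
            sid = f"{sp}{i + 1:02d}"
            if hybrid_left > 0 and i == n_per_species - 1 and n_species >= 2:
                other = species_names[(k + 1) % n_species]
                a1, a2 = draw_allele(sp), draw_allele(other)
                samples.append((sid, sp, a1.tobytes().decode(), a2.tobytes().decode()))
                hybrid_left -= 1
                continue
            if rng.random() < heterozygosity:
                a1, a2 = draw_allele(sp), draw_allele(sp)
                samples.append((sid, sp, a1.tobytes().decode(), a2.tobytes().decode()))
            else:
                a1 = draw_allele(sp)
                samples.append((sid, sp, a1.tobytes().decode(), None))

    tree = _star_allele_tree(samples, half, within)
    params = dict(
        n_per_species=n_per_species, n_species=n_species, seq_length=seq_length,
        divergence=divergence, heterozygosity=heterozygosity,
        hybrid_samples=hybrid_samples, seed=seed,
    )
    return SimulatedGenotypeSet(samples, tree, params)


def _star_allele_tree(samples, half: float, within: float) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    species_nodes: dict[str, dendropy.Node] = {}
    for sid, sp, a1, a2 in samples:
        if sp not in species_nodes:
            node = tree.seed_node.new_child(edge_length=max(0.0, half - within))
            species_nodes[sp] = node
        labels = [sid] if a2 is None else [f"{sid}-1", f"{sid}-2"]
        for lab in labels:
            leaf = species_nodes[sp].new_child(edge_length=within)
            leaf.taxon = taxa.new_taxon(lab)
    return tree


# ----------------------------------------------------------------------
# Coupled morphology/genetics datasets
# ----------------------------------------------------------------------

def default_species_params() -> dict[str, dict]:
    """Synthetic species with contrasting thickness / spacing / length ratio.

    Chosen once as plausible for thin-branching Madracis-like colonies:
    branch radii 1.5–3.5 mm, branch lengths 12–20 mm, inter-child angles
    35–55 degrees.
    """
    return {
        "SpA": dict(mean_radius=1.5, mean_branch_length=13.0, branch_angle=55.0,
                    n_generations=3, angle_jitter=4.0),
        "SpB": dict(mean_radius=2.5, mean_branch_length=16.0, branch_angle=42.0,
                    n_generations=3, angle_jitter=4.0),
        "SpC": dict(mean_radius=3.5, mean_branch_length=20.0, branch_angle=34.0,
                    n_generations=3, angle_jitter=4.0),
    }


def generate_congruent_dataset(
    effect_size: float,
    n_samples: int,
    seed: int,
    *,
    n_species: int = 3,
    divergence: float = 0.05,
    heterozygosity: float = 0.4,
    seq_length: int = 400,
) -> tuple[FeatureMatrix, DistanceMatrix, dict[str, str]]:
    """Paired morphology features and genetic distances with tunable congruence.

    Morphological traits are drawn from species-specific trivariate normals
    with unit within-species s.d. and between-species mean separation
    ``effect_size`` (in within-species s.d. units).  Genetic distances come
    from :func:`simulate_genotypes` on the same species assignment, so
    ``effect_size=0`` makes the two matrices independent while large values
    make the Mantel/CADM tests reject with high power.

    Returns (features, genetic distance matrix, sample -> species map).
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    from .genetics import genetic_distance_matrix, SampleGenotype

    rng = np.random.default_rng(seed)
    base = n_samples // n_species
    counts = [base + (1 if k < n_samples % n_species else 0) for k in range(n_species)]

    # species mean trait vectors on a simplex-like arrangement, scaled by effect size
    dirs = rng.standard_normal((n_species, 3))
    dirs -= dirs.mean(axis=0)
    dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-9)
    means = effect_size * dirs

    gset = simulate_genotypes(
        n_per_species=max(counts), n_species=n_species, seq_length=seq_length,
        divergence=divergence, heterozygosity=heterozygosity,
        hybrid_samples=0, seed=int(rng.integers(0, 2**31 - 1)),
    )
    # trim to the exact per-species counts
    kept: list[tuple[str, str, str, str | None]] = []
    for k, sp in enumerate(sorted({s[1] for s in gset.samples})):
        sp_samples = [s for s in gset.samples if s[1] == sp]
        kept.extend(sp_samples[: counts[k]])

    genotypes = [SampleGenotype(sid, sp, [a for a in (a1, a2) if a is not None])
                 for sid, sp, a1, a2 in kept]
    gdm = genetic_distance_matrix(genotypes)

    ids, species_map, rows = [], {}, []
    for k, sp in enumerate(sorted({s[1] for s in kept})):
        for sid, _sp, _a, _b in [s for s in kept if s[1] == sp]:
            ids.append(sid)
            species_map[sid] = sp
            rows.append(means[k] + rng.standard_normal(3))
    features = FeatureMatrix(ids, ["thickness", "spacing", "length_thickness_ratio"], np.array(rows))
    gdm = gdm.reorder(ids)
    return features, gdm, species_map
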