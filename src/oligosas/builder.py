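"""Coarse-grained conformer construction for a flexible three-part protein.

The target architecture mirrors the bacterial replication initiator DnaA:
a small N-terminal rigid head (domain I, residues 1-108), an unstructured
flexible linker (domain II, residues 109-129), and a large rigid core
(the AAA+ and DNA-binding domains III-IV, residues 130-467). Models are
one bead per residue (Calpha level) with a uniform scattering amplitude.

Conformers keep the core fixed in a common frame while the linker is
resampled as a constrained random walk and the head is rigidly re-attached
with a random orientation — the "domains I and II move, III-IV held fixed"
sampling contract. Oligomers (dimer..pentamer) place copies of the core by
head-to-tail application of a helical interface transform (rotation about
an axis plus a translation of one core diameter per step), each protomer
receiving its own independently sampled linker and head.

Rigid bodies default to programmatic self-avoiding globules so the
pipeline runs without any structure download; Calpha coordinates can be
substituted from a PDB file when available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .scatter import debye_intensity

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    """Raised when stochastic model construction exhausts its retry budget."""


# ---------------------------------------------------------------------------
# architecture


@dataclass(frozen=True)
class DomainArchitecture:
    """Residue spans of the head / linker / core parts (inclusive, 1-based)."""

    rigid_head: tuple[int, int] = (1, 108)
    linker: tuple[int, int] = (109, 129)
    rigid_core: tuple[int, int] = (130, 467)
    residue_step: float = 3.8       # Calpha-Calpha bond length, A
    clash_distance: float = 3.0     # minimum bead-bead separation, A
    globule_r0: float = 2.4         # Rg ~ r0 * n^(1/3) for rigid globules, A
    linker_cone_deg: float = 120.0  # max per-step direction deviation
    max_resample: int = 200         # per-conformer rejection budget

    def __post_init__(self) -> None:
        spans = [self.rigid_head, self.linker, self.rigid_core]
        if self.rigid_head[0] != 1:
            raise ValueError("head span must start at residue 1")
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if a > b or c != b + 1:
                raise ValueError("spans must be contiguous, ordered, non-overlapping")

    @property
    def n_head(self) -> int:
        return self.rigid_head[1] - self.rigid_head[0] + 1

    @property
    def n_linker(self) -> int:
        return self.linker[1] - self.linker[0] + 1

    @property
    def n_core(self) -> int:
        return self.rigid_core[1] - self.rigid_core[0] + 1

    @property
    def n_residues(self) -> int:
        return self.rigid_core[1]


@dataclass
class BeadModel:
    """One conformer: bead coordinates plus bookkeeping.

    ``coords`` is ordered by residue within each protomer (head, linker,
    core) and protomer-major for oligomers. ``rg`` always equals the
    root-mean-square distance of the beads from their centroid.
    """

    coords: np.ndarray
    oligomer_order: int
    scattering_amplitude: float = 1.0
    rg: float = 0.0
    domain_labels: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not 1 <= self.oligomer_order <= 5:
            raise ValueError("oligomer_order must be in 1..5")
        if self.rg == 0.0:
            self.rg = compute_rg(self.coords)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


def compute_rg(coords: np.ndarray) -> float:
    """Root-mean-square distance of beads from their centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c * c, axis=1))))


# ---------------------------------------------------------------------------
# rigid bodies


def make_rigid_body(n_residues: int, shape: str = "globule", seed: int = 0,
                    r0: float = 2.4, clash_distance: float = 3.0,
                    max_attempts: int = 20000,
                    attachment: str | None = None) -> np.ndarray:
    """Programmatic compact rigid body: a self-avoiding globule.

    Beads are placed by rejection sampling uniformly inside a sphere whose
    radius is chosen so that Rg ~= r0 * n^(1/3) (the empirical compact-
    globule scaling), subject to a minimum pairwise separation. The result
    is centered on its centroid and deterministic for a given seed.

    ``attachment`` ("first" or "last") moves the bead farthest from the
    centroid to that position, making it the linker attachment point — a
    terminal residue sits on the domain surface, not in its interior.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if shape != "globule":
        raise ValueError(f"unknown shape {shape!r}")
    rng = np.random.default_rng(seed)
    radius = np.sqrt(5.0 / 3.0) * r0 * n_residues ** (1.0 / 3.0)
    placed = np.empty((n_residues, 3))
    n_placed = 0
    for _ in range(max_attempts):
        # uniform in the ball
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        p = radius * rng.random() ** (1.0 / 3.0) * v
        if n_placed and np.min(np.linalg.norm(placed[:n_placed] - p, axis=1)) < clash_distance:
            continue
        placed[n_placed] = p
        n_placed += 1
        if n_placed == n_residues:
            coords = placed - placed.mean(axis=0)
            if attachment is not None:
                far = int(np.argmax(np.sum(coords * coords, axis=1)))
                dest = 0 if attachment == "first" else n_residues - 1
                coords[[dest, far]] = coords[[far, dest]]
            return coords
    raise GenerationError(
        f"globule packing failed: placed {n_placed}/{n_residues} beads "
        f"in {max_attempts} attempts"
    )


def load_rigid_body_pdb(path: str | Path, span: tuple[int, int],
                        chain: str | None = None) -> np.ndarray:
    """Extract one bead per residue at the Calpha position from a PDB file.

    Missing residues within the span are reported via a logged warning;
    for alternate locations the highest-occupancy altLoc is kept.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("rigid", str(path))
    model = next(structure.get_models())
    coords: dict[int, np.ndarray] = {}
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            resseq = res.id[1]
            if not (span[0] <= resseq <= span[1]) or resseq in coords:
                continue
            best_ca, best_occ = None, -1.0
            for atom in res:
                if atom.get_name() != "CA":
                    continue
                if atom.is_disordered():
                    for alt in atom.disordered_get_list():
                        occ = alt.get_occupancy() or 0.0
                        if occ > best_occ:
                            best_ca, best_occ = alt, occ
                else:
                    occ = atom.get_occupancy() or 0.0
                    if occ > best_occ:
                        best_ca, best_occ = atom, occ
            if best_ca is not None:
                coords[resseq] = np.asarray(best_ca.get_coord(), dtype=float)
    if not coords:
        raise ValueError(f"{path}: no Calpha records in residue span {span}")
    missing = sorted(set(range(span[0], span[1] + 1)) - set(coords))
    if missing:
        logger.warning("%s: missing residues in span %s: %s", path, span, missing)
    arr = np.array([coords[r] for r in sorted(coords)])
    return arr - arr.mean(axis=0)


# ---------------------------------------------------------------------------
# linker sampling


def _jitter_direction(rng: np.random.Generator, direction: np.ndarray,
                      cone_deg: float) -> np.ndarray:
    """Rotate ``direction`` by a polar angle uniform in [0, cone] with a
    uniform azimuth."""
    theta = np.deg2rad(cone_deg) * rng.random()
    phi = 2.0 * np.pi * rng.random()
    # orthonormal frame around direction
    d = direction / np.linalg.norm(direction)
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return (np.cos(theta) * d
            + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))


def sample_linker(anchor_pos: np.ndarray, anchor_dir: np.ndarray,
                  n_residues: int, step: float = 3.8, seed: int = 0,
                  cone_deg: float = 120.0, obstacles: np.ndarray | None = None,
                  clash_distance: float = 3.0,
                  max_resample: int = 200) -> np.ndarray:
    """Constrained random walk for the flexible linker.

    Each bead continues the previous direction deviated by an angle drawn
    uniformly within the cone; steps clashing with ``obstacles`` or with
    already-placed linker beads are resampled. Deterministic given seed.
    """
    if n_residues < 1:
        raise ValueError("linker needs at least one residue")
    rng = np.random.default_rng(seed)
    tree = cKDTree(obstacles) if obstacles is not None and len(obstacles) else None
    beads = np.empty((n_residues, 3))
    pos = np.asarray(anchor_pos, dtype=float)
    direction = np.asarray(anchor_dir, dtype=float)
    for k in range(n_residues):
        for attempt in range(max_resample + 1):
            d = _jitter_direction(rng, direction, cone_deg)
            cand = pos + step * d
            ok = True
            if tree is not None and tree.query(cand, k=1)[0] < clash_distance:
                ok = False
            if ok and k > 1:
                # bead k-1 is the bonded neighbour at exactly `step`
                if np.min(np.linalg.norm(beads[:k - 1] - cand, axis=1)) < clash_distance:
                    ok = False
            if ok:
                beads[k] = cand
                pos, direction = cand, d
                break
        else:
            raise GenerationError(
                f"linker sampling: rejection limit {max_resample} exceeded at bead {k}"
            )
    return beads


# ---------------------------------------------------------------------------
# conformer assembly


def _attach_head(rng: np.random.Generator, head_coords: np.ndarray,
                 linker_end: np.ndarray, outward: np.ndarray, step: float,
                 obstacles_tree: cKDTree, clash_distance: float,
                 max_resample: int) -> np.ndarray:
    """Rigidly place the head with a random orientation, its attachment
    bead (last of the head span) one bond step from the linker's free end.

    The bond direction is drawn in a cone around ``outward`` (the last
    linker step) and the orientation uniformly at random, rejected on
    clash — uniform over the clash-free orientations reachable from the
    linker end.
    """
    attach_local = head_coords[-1]
    body = head_coords - attach_local
    for _ in range(max_resample + 1):
        rot = Rotation.random(rng=rng).as_matrix()
        d = _jitter_direction(rng, outward, 90.0)
        placed = body @ rot.T + (linker_end + step * d)
        if obstacles_tree.query(placed, k=1)[0].min() >= clash_distance:
            return placed
    raise GenerationError("head placement: rejection limit exceeded")


def _domain_labels(arch: DomainArchitecture) -> np.ndarray:
    return np.array(["head"] * arch.n_head + ["linker"] * arch.n_linker
                    + ["core"] * arch.n_core)


def _build_protomer_flex(arch: DomainArchitecture, core_placed: np.ndarray,
                         head_coords: np.ndarray, obstacles: np.ndarray,
                         rng_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample linker+head for one protomer whose core is already placed.

    Returns (linker_beads residue-ordered 109..129, head_beads 1..108).
    """
    rng = np.random.default_rng(rng_seed)
    attach = core_placed[0]                      # first bead of the core span
    centroid = core_placed.mean(axis=0)
    outward = attach - centroid
    if np.linalg.norm(outward) < 1e-9:
        outward = np.array([0.0, 0.0, 1.0])
    # walk from residue 129 down to 109 (away from the core)
    walk = sample_linker(
        attach, outward, arch.n_linker, step=arch.residue_step,
        seed=int(rng.integers(2 ** 31)), cone_deg=arch.linker_cone_deg,
        obstacles=obstacles, clash_distance=arch.clash_distance,
        max_resample=arch.max_resample)
    linker = walk[::-1].copy()                   # residue order 109..129
    obstacles_now = np.vstack([obstacles, walk])
    outward = walk[-1] - (walk[-2] if arch.n_linker > 1 else attach)
    head = _attach_head(rng, head_coords, walk[-1], outward,
                        arch.residue_step, cKDTree(obstacles_now),
                        arch.clash_distance, arch.max_resample)
    return linker, head


def build_conformer(arch: DomainArchitecture, core_coords: np.ndarray,
                    head_coords: np.ndarray, seed: int = 0) -> BeadModel:
    """One monomer conformer: fixed core, freshly sampled linker + head."""
    if core_coords.shape[0] != arch.n_core:
        raise ValueError("core coordinate count does not match the core span")
    if head_coords.shape[0] != arch.n_head:
        raise ValueError("head coordinate count does not match the head span")
    last_err: Exception | None = None
    for retry in range(25):
        try:
            linker, head = _build_protomer_flex(
                arch, core_coords, head_coords, core_coords,
                rng_seed=_mix_seed(seed, retry))
            coords = np.vstack([head, linker, core_coords])
            return BeadModel(coords=coords, oligomer_order=1,
                             domain_labels=_domain_labels(arch),
                             source_id=f"monomer-{seed}")
        except GenerationError as exc:
            last_err = exc
    raise GenerationError(f"build_conformer: retries exhausted ({last_err})")


def _interface_positions(core: np.ndarray, order: int, angle_deg: float,
                         translation: float | None,
                         clash_distance: float = 3.0) -> list[np.ndarray]:
    """Head-to-tail helical placement of ``order`` core copies.

    Each step rotates by ``angle_deg`` about z and translates so that
    consecutive core centroids are one core diameter apart. The default
    diameter is twice the maximum radial extent plus the clash distance,
    which provably keeps any two copies clash-free.
    """
    if translation is None:
        centered = core - core.mean(axis=0)
        translation = 2.0 * float(np.linalg.norm(centered, axis=1).max()) \
            + clash_distance
    theta = np.deg2rad(angle_deg)
    rz = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                   [np.sin(theta), np.cos(theta), 0.0],
                   [0.0, 0.0, 1.0]])
    v = np.array([translation, 0.0, 0.0])
    placed = [core.copy()]
    rot = np.eye(3)
    offset = np.zeros(3)
    for _ in range(1, order):
        rot = rz @ rot
        offset = rz @ offset + v
        placed.append(core @ rot.T + offset)
    return placed


def assemble_oligomer(arch: DomainArchitecture, protomer_core: np.ndarray,
                      head_coords: np.ndarray, order: int, seed: int = 0,
                      interface_angle_deg: float = 60.0,
                      interface_translation: float | None = None) -> BeadModel:
    """Build an oligomer conformer of the given order (2..5 — order 1 is
    delegated to :func:`build_conformer`).

    Core copies are placed by the helical interface transform; every
    protomer then receives its own independently sampled linker and head.
    """
    if order == 1:
        return build_conformer(arch, protomer_core, head_coords, seed=seed)
    if not 2 <= order <= 5:
        raise ValueError("order must be in 1..5")
    cores = _interface_positions(protomer_core, order, interface_angle_deg,
                                 interface_translation, arch.clash_distance)
    all_cores = np.vstack(cores)
    # inter-core clash check (deterministic for a fixed core/transform)
    for a in range(order):
        for b in range(a + 1, order):
            if cdist(cores[a], cores[b]).min() < arch.clash_distance:
                raise GenerationError(
                    "inter-protomer core clash: increase the interface "
                    "translation or change the rotation angle")
    last_err: Exception | None = None
    for retry in range(25):
        try:
            blocks = []
            obstacles = all_cores
            for k in range(order):
                linker, head = _build_protomer_flex(
                    arch, cores[k], head_coords, obstacles,
                    rng_seed=_mix_seed(seed, 101 * k + retry))
                blocks.append(np.vstack([head, linker, cores[k]]))
                obstacles = np.vstack([obstacles, linker, head])
            coords = np.vstack(blocks)
            return BeadModel(coords=coords, oligomer_order=order,
                             domain_labels=np.tile(_domain_labels(arch), order),
                             source_id=f"{order}mer-{seed}")
        except GenerationError as exc:
            last_err = exc
    raise GenerationError(
        f"assemble_oligomer(order={order}): retries exhausted ({last_err})")


def _mix_seed(*parts: int) -> int:
    """Deterministically combine seed components into one 31-bit seed."""
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# pools


@dataclass
class ConformerPool:
    """Per-oligomer-state conformer collections with precomputed curves.

    ``curves[order]`` is an (n_conformers, n_q) array of per-particle
    Debye intensities on ``q_grid``; ``rg[order]`` the matching Rg values.
    ``models`` holds the BeadModel objects when the pool was built in
    memory (dropped on serialization — conformers are regenerable from
    the recorded seed).
    """

    q_grid: np.ndarray
    curves: dict[int, np.ndarray]
    rg: dict[int, np.ndarray]
    seed: int
    arch: DomainArchitecture = field(default_factory=DomainArchitecture)
    models: dict[int, list[BeadModel]] | None = None

    @property
    def orders(self) -> list[int]:
        return sorted(self.curves)

    def n_per_state(self) -> dict[int, int]:
        return {o: self.curves[o].shape[0] for o in self.orders}

    def subset(self, keep: dict[int, np.ndarray]) -> "ConformerPool":
        """Pool restricted to the given per-state index arrays."""
        return ConformerPool(
            q_grid=self.q_grid,
            curves={o: self.curves[o][idx] for o, idx in keep.items()},
            rg={o: self.rg[o][idx] for o, idx in keep.items()},
            seed=self.seed, arch=self.arch,
            models={o: [self.models[o][i] for i in idx] for o, idx in keep.items()}
            if self.models is not None else None)

    def save(self, directory: str | Path) -> None:
        """NPZ container (curves, rg, q grid) plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {"q_grid": self.q_grid}
        for o in self.orders:
            arrays[f"curves_{o}"] = self.curves[o]
            arrays[f"rg_{o}"] = self.rg[o]
        np.savez_compressed(directory / "pool.npz", **arrays)
        manifest = {
            "seed": self.seed,
            "orders": self.orders,
            "n_per_state": self.n_per_state(),
            "n_q": int(self.q_grid.size),
            "architecture": {
                "rigid_head": list(self.arch.rigid_head),
                "linker": list(self.arch.linker),
                "rigid_core": list(self.arch.rigid_core),
                "residue_step": self.arch.residue_step,
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "ConformerPool":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        data = np.load(directory / "pool.npz")
        arch_d = manifest["architecture"]
        arch = DomainArchitecture(
            rigid_head=tuple(arch_d["rigid_head"]), linker=tuple(arch_d["linker"]),
            rigid_core=tuple(arch_d["rigid_core"]),
            residue_step=arch_d["residue_step"])
        curves = {o: data[f"curves_{o}"] for o in manifest["orders"]}
        rg = {o: data[f"rg_{o}"] for o in manifest["orders"]}
        return cls(q_grid=data["q_grid"], curves=curves, rg=rg,
                   seed=manifest["seed"], arch=arch)


def generate_pool(arch: DomainArchitecture, orders, n_per_state: int,
                  q_grid: np.ndarray, seed: int = 0,
                  core_coords: np.ndarray | None = None,
                  head_coords: np.ndarray | None = None,
                  keep_models: bool = True) -> ConformerPool:
    """Generate a per-state conformer pool with precomputed Debye curves.

    The rigid core and head bodies are generated once from the master seed
    (or supplied, e.g. from PDB Calpha extraction) and shared by every
    conformer, so core coordinates are bit-identical across a state.
    Full-scale pools use 10000 conformers per state; 500 is a practical
    desk-scale default.
    """
    orders = sorted(set(int(o) for o in orders))
    if not orders or not all(1 <= o <= 5 for o in orders):
        raise ValueError("orders must be a non-empty subset of 1..5")
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    if core_coords is None:
        core_coords = make_rigid_body(arch.n_core, seed=_mix_seed(seed, 101),
                                      r0=arch.globule_r0,
                                      clash_distance=arch.clash_distance,
                                      attachment="first")
    if head_coords is None:
        head_coords = make_rigid_body(arch.n_head, seed=_mix_seed(seed, 202),
                                      r0=arch.globule_r0,
                                      clash_distance=arch.clash_distance,
                                      attachment="last")
    curves: dict[int, np.ndarray] = {}
    rgs: dict[int, np.ndarray] = {}
    models: dict[int, list[BeadModel]] = {}
    for order in orders:
        state_models: list[BeadModel] = []
        state_curves = np.empty((n_per_state, q_grid.size))
        state_rg = np.empty(n_per_state)
        for i in range(n_per_state):
            try:
                m = assemble_oligomer(arch, core_coords, head_coords, order,
                                      seed=_mix_seed(seed, order, i))
            except GenerationError as exc:
                raise GenerationError(f"state {order}, conformer {i}: {exc}") from exc
            m.source_id = f"s{order}c{i}"
            state_models.append(m)
            state_curves[i] = debye_intensity(m, q_grid, mode="auto").intensity
            state_rg[i] = m.rg
        curves[order] = state_curves
        rgs[order] = state_rg
        models[order] = state_models
        logger.info("pool: state %d done (%d conformers)", order, n_per_state)
    return ConformerPool(q_grid=np.asarray(q_grid, dtype=float), curves=curves,
                         rg=rgs, seed=seed, arch=arch,
                         models=models if keep_models else None)
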