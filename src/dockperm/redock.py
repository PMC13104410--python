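"""Redocking accuracy: in-place heavy-atom RMSD, success rates, report table.

Redocking validation asks whether a docking algorithm can reproduce the
crystallographic binding mode of a co-crystallised ligand.  The measure is
the heavy-atom RMSD between the reference ligand and each docked pose,
computed *in the receptor frame* — no re-superposition — so that both
conformational and positional error count.  A ligand is redocked
successfully when its pose RMSD falls strictly below a cutoff (2 Å by
convention), and the success rate over a set of ligands is

    success rate = (number of ligands with RMSD < cutoff / total) × 100.

:class:`RedockingValidation` is the model object: it holds, per
(structure, docking algorithm), the pose ensembles of each ligand, and its
:meth:`~RedockingValidation.fit` computes all pose RMSDs, the best pose per
ligand, the top-ranked pose per scoring function, success rates and column
average RMSDs, returning a :class:`RedockingResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .pose_io import Conformer, PoseSet, PoseValidationError, heavy_atom_view

__all__ = [
    "AutomorphismLimitError",
    "inplace_rmsd",
    "graph_automorphisms",
    "best_pose",
    "top_pose_index",
    "top_pose_rmsd",
    "success_rate",
    "SuccessRate",
    "average_rmsd",
    "PoseComparison",
    "RedockEntry",
    "redock_table",
    "RedockingValidation",
    "RedockingResults",
]

AUTOMORPHISM_CAP = 10_000


class AutomorphismLimitError(RuntimeError):
    """The automorphism search exceeded the enumeration cap."""


def graph_automorphisms(conf: Conformer, cap: int = AUTOMORPHISM_CAP) -> list[dict[int, int]]:
    """Element- and bond-preserving atom permutations of a conformer.

    The molecular graph (nodes = atoms labelled by element, edges = bonds
    labelled by order) is matched onto itself with networkx's VF2 matcher.
    Enumeration is exhaustive with a hard cap; exceeding the cap raises
    :class:`AutomorphismLimitError`.  A conformer without bonds has every
    element-preserving permutation as an automorphism, which for repeated
    elements blows through the cap quickly — supply bonds for symmetry work.
    """
    import networkx as nx
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_edge_match, categorical_node_match

    g = nx.Graph()
    for atom in conf.atoms:
        g.add_node(atom.index, element=atom.element)
    for i, j, order in conf.bonds:
        g.add_edge(i, j, order=order)
    matcher = GraphMatcher(
        g,
        g,
        node_match=categorical_node_match("element", None),
        edge_match=categorical_edge_match("order", None),
    )
    mappings: list[dict[int, int]] = []
    for mapping in matcher.isomorphisms_iter():
        mappings.append(mapping)
        if len(mappings) > cap:
            raise AutomorphismLimitError(
                f"more than {cap} automorphisms for '{conf.name}'"
            )
    return mappings


def _check_comparable(ref: Conformer, pose: Conformer) -> tuple[Conformer, Conformer]:
    ref_h = heavy_atom_view(ref)
    pose_h = heavy_atom_view(pose)
    if len(ref_h) != len(pose_h):
        raise PoseValidationError(
            f"heavy-atom count mismatch: reference {len(ref_h)} vs pose {len(pose_h)}"
        )
    if ref_h.element_multiset() != pose_h.element_multiset():
        raise PoseValidationError("heavy-atom element multiset mismatch")
    return ref_h, pose_h


def inplace_rmsd(ref: Conformer, pose: Conformer, symmetry: bool = False) -> float:
    """Heavy-atom RMSD between reference and pose, without re-superposition.

    With ``symmetry=True`` the RMSD is minimised over the graph automorphisms
    of the reference (topologically equivalent atoms may swap, e.g. the two
    ortho/meta pairs of a para-substituted phenyl), which can only lower the
    value.  Default off, matching typical docking-suite output.
    """
    ref_h, pose_h = _check_comparable(ref, pose)
    a = ref_h.coords
    b = pose_h.coords
    identity = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    if not symmetry:
        return identity
    best = identity
    for mapping in graph_automorphisms(ref_h):
        perm = [mapping[i] for i in range(len(ref_h))]
        d = float(np.sqrt(np.mean(np.sum((a[perm] - b) ** 2, axis=1))))
        if d < best:
            best = d
    return best


def best_pose(rmsds: Sequence[float]) -> tuple[float, int]:
    """Minimum RMSD over an ensemble and its 1-based pose rank (file order).

    Ties go to the lowest rank.
    """
    if len(rmsds) == 0:
        raise ValueError("empty RMSD list")
    arr = np.asarray(rmsds, dtype=float)
    idx = int(np.argmin(arr))
    return float(arr[idx]), idx + 1


def top_pose_index(scores: Sequence[float], orientation: str = "higher") -> int:
    """0-based index of the best-scoring pose; ties keep the earliest pose."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score vector")
    return int(np.argmin(arr)) if orientation == "lower" else int(np.argmax(arr))


def top_pose_rmsd(
    pose_set: PoseSet,
    function: str,
    orientation: str = "higher",
    symmetry: bool = False,
    rmsds: Sequence[float] | None = None,
) -> tuple[float, int]:
    """RMSD of the pose ranked first by a scoring function, with its rank.

    ``rmsds`` may carry precomputed per-pose RMSDs to avoid recomputation.
    """
    if function not in pose_set.scores:
        raise KeyError(f"no score vector '{function}' for '{pose_set.ligand_id}'")
    idx = top_pose_index(pose_set.scores[function], orientation)
    if rmsds is not None:
        value = float(rmsds[idx])
    else:
        value = inplace_rmsd(pose_set.reference, pose_set.poses[idx], symmetry)
    return value, idx + 1


@dataclass(frozen=True)
class SuccessRate:
    """Redocking success rate with its counts; strict '< cutoff' rule."""

    n_success: int
    n_total: int
    cutoff: float = 2.0

    @property
    def percent(self) -> float:
        return 100.0 * self.n_success / self.n_total

    @property
    def rounded(self) -> int:
        """Whole-percent value for reporting (half away from zero)."""
        return int(round_half_up(self.percent, 0))

    def __float__(self) -> float:
        return self.percent


def success_rate(rmsds: Sequence[float], cutoff: float = 2.0) -> SuccessRate:
    """Fraction of ligands redocked with RMSD strictly below the cutoff."""
    if len(rmsds) == 0:
        raise ValueError("empty RMSD list")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    arr = np.asarray(rmsds, dtype=float)
    return SuccessRate(int((arr < cutoff).sum()), int(arr.size), cutoff)


def average_rmsd(rmsds: Sequence[float]) -> float:
    """Arithmetic mean RMSD (reported to 1 decimal in summary tables)."""
    if len(rmsds) == 0:
        raise ValueError("empty RMSD list")
    return float(np.mean(np.asarray(rmsds, dtype=float)))


@dataclass(frozen=True)
class PoseComparison:
    """RMSD of one pose against the reference."""

    ligand_id: str
    pose_index: int  # 0-based, file order
    rmsd: float
    mapping: str = "identity"  # or "symmetry-corrected"

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


@dataclass
class RedockEntry:
    """Per-(structure, algorithm, ligand) outcome of a redocking run."""

    structure: str
    algorithm: str
    ligand: str
    n_poses: int
    best_rmsd: float
    best_rank: int
    top: dict[str, tuple[float, int]] = field(default_factory=dict)  # function -> (rmsd, rank)


class RedockingValidation:
    """Model: redocking experiments per (structure, docking algorithm).

    Parameters
    ----------
    pose_sets
        Mapping ``(structure, algorithm) -> list of PoseSet`` (one per
        co-crystallised ligand; each pose set carries the reference
        conformer, the docked ensemble in file order, and per-function
        score vectors).
    cutoff
        Success cutoff in Å (strict ``<``).
    symmetry
        Minimise RMSD over graph automorphisms of the reference.
    orientations
        Better-score direction per scoring function (default 'higher').
    """

    def __init__(
        self,
        pose_sets: Mapping[tuple[str, str], Sequence[PoseSet]],
        cutoff: float = 2.0,
        symmetry: bool = False,
        orientations: Mapping[str, str] | None = None,
    ) -> None:
        self.pose_sets = {k: list(v) for k, v in pose_sets.items()}
        self.cutoff = float(cutoff)
        self.symmetry = bool(symmetry)
        self.orientations = dict(orientations or {})

    def fit(self) -> "RedockingResults":
        entries: list[RedockEntry] = []
        for (structure, algorithm), sets in self.pose_sets.items():
            for ps in sets:
                rmsds = [
                    inplace_rmsd(ps.reference, pose, self.symmetry)
                    for pose in ps.poses
                ]
                b_rmsd, b_rank = best_pose(rmsds)
                top = {
                    fn: top_pose_rmsd(
                        ps, fn, self.orientations.get(fn, "higher"), rmsds=rmsds
                    )
                    for fn in ps.scores
                }
                entries.append(
                    RedockEntry(
                        structure=structure,
                        algorithm=algorithm,
                        ligand=ps.ligand_id,
                        n_poses=ps.n_poses,
                        best_rmsd=b_rmsd,
                        best_rank=b_rank,
                        top=top,
                    )
                )
        return RedockingResults(entries, cutoff=self.cutoff)

    @classmethod
    def from_entries(
        cls, entries: Iterable[RedockEntry], cutoff: float = 2.0
    ) -> "RedockingResults":
        """Build results directly from precomputed per-ligand outcomes."""
        return RedockingResults(list(entries), cutoff=cutoff)


BEST_COLUMN = "Best pose"


class RedockingResults:
    """Per-ligand RMSD outcomes plus success-rate / average-RMSD summaries."""

    def __init__(self, entries: Sequence[RedockEntry], cutoff: float = 2.0) -> None:
        if not entries:
            raise ValueError("no redocking entries")
        self.entries = list(entries)
        self.cutoff = float(cutoff)
        self._check_consistent_ligands()

    def _check_consistent_ligands(self) -> None:
        per_combo: dict[tuple[str, str], set[str]] = {}
        for e in self.entries:
            per_combo.setdefault((e.structure, e.algorithm), set()).add(e.ligand)
        by_structure: dict[str, set[frozenset]] = {}
        for (structure, _), ligands in per_combo.items():
            by_structure.setdefault(structure, set()).add(frozenset(ligands))
        for structure, ligand_sets in by_structure.items():
            if len(ligand_sets) > 1:
                raise ValueError(
                    f"inconsistent ligand sets across algorithms for {structure}"
                )

    # -- selectors ---------------------------------------------------------

    def _select(self, structure: str, algorithm: str) -> list[RedockEntry]:
        sel = [
            e
            for e in self.entries
            if e.structure == structure and e.algorithm == algorithm
        ]
        if not sel:
            raise KeyError(f"no entries for ({structure}, {algorithm})")
        return sel

    def functions(self, structure: str, algorithm: str) -> list[str]:
        sel = self._select(structure, algorithm)
        fns = list(sel[0].top)
        for e in sel[1:]:
            if list(e.top) != fns:
                raise ValueError("inconsistent scoring functions across ligands")
        return fns

    def structures(self) -> list[str]:
        seen = dict.fromkeys(e.structure for e in self.entries)
        return list(seen)

    def algorithms(self, structure: str) -> list[str]:
        seen = dict.fromkeys(
            e.algorithm for e in self.entries if e.structure == structure
        )
        return list(seen)

    # -- column statistics -------------------------------------------------

    def column_rmsds(self, structure: str, algorithm: str, column: str) -> list[float]:
        sel = self._select(structure, algorithm)
        if column == BEST_COLUMN:
            return [e.best_rmsd for e in sel]
        return [e.top[column][0] for e in sel]

    def success_rates(self, structure: str, algorithm: str) -> dict[str, SuccessRate]:
        cols = [BEST_COLUMN] + self.functions(structure, algorithm)
        return {
            c: success_rate(self.column_rmsds(structure, algorithm, c), self.cutoff)
            for c in cols
        }

    def average_rmsds(self, structure: str, algorithm: str) -> dict[str, float]:
        cols = [BEST_COLUMN] + self.functions(structure, algorithm)
        return {
            c: average_rmsd(self.column_rmsds(structure, algorithm, c)) for c in cols
        }

    def overall_success_rates(self, structure: str) -> dict[str, SuccessRate]:
        """Success rate per column with ligand counts pooled over algorithms."""
        algos = self.algorithms(structure)
        cols = [BEST_COLUMN] + self.functions(structure, algos[0])
        pooled: dict[str, SuccessRate] = {}
        for c in cols:
            n_s = n_t = 0
            for algo in algos:
                sr = success_rate(self.column_rmsds(structure, algo, c), self.cutoff)
                n_s += sr.n_success
                n_t += sr.n_total
            pooled[c] = SuccessRate(n_s, n_t, self.cutoff)
        return pooled

    # -- report ------------------------------------------------------------

    def summary(self, structure: str | None = None) -> pd.DataFrame:
        """Report table: per-ligand RMSD (rank), totals, success %, mean RMSD.

        Rows are indexed by (structure, algorithm, row); the best-pose column
        comes first, then one column per scoring function.  Success rates are
        whole percent, averages 1-decimal, per reporting convention.
        """
        structures = [structure] if structure else self.structures()
        blocks = []
        for s in structures:
            for algo in self.algorithms(s):
                sel = self._select(s, algo)
                cols = [BEST_COLUMN] + self.functions(s, algo)
                rows = {}
                for e in sel:
                    cells = {BEST_COLUMN: f"{e.best_rmsd:.2f} ({e.best_rank})"}
                    for fn, (r, rk) in e.top.items():
                        cells[fn] = f"{r:.2f} ({rk})"
                    rows[f"{e.ligand} ({e.n_poses})"] = cells
                srs = self.success_rates(s, algo)
                rows["Total"] = {c: srs[c].n_success for c in cols}
                rows["Success rate (%)"] = {c: srs[c].rounded for c in cols}
                avgs = self.average_rmsds(s, algo)
                rows["Average RMSD"] = {c: round_half_up(avgs[c], 1) for c in cols}
                frame = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
                frame.index = pd.MultiIndex.from_product([[s], [algo], frame.index])
                blocks.append(frame)
            if len(self.algorithms(s)) > 1:
                overall = self.overall_success_rates(s)
                cols = list(overall)
                frame = pd.DataFrame(
                    {c: [overall[c].rounded] for c in cols},
                    index=pd.MultiIndex.from_product(
                        [[s], ["(all)"], ["Overall success rate (%)"]]
                    ),
                )
                blocks.append(frame)
        return pd.concat(blocks)


def redock_table(
    results_or_entries: RedockingResults | Iterable[RedockEntry],
    cutoff: float = 2.0,
) -> pd.DataFrame:
    """Convenience wrapper: the full report table for a set of entries."""
    if isinstance(results_or_entries, RedockingResults):
        return results_or_entries.summary()
    return RedockingResults(list(results_or_entries), cutoff=cutoff).summary()
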