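"""Spatial clustering of mutated residues on a protein structure.

Mutated residues are mapped to Cα coordinates and summarized by a transparent
statistic — the mean pairwise Euclidean Cα distance — whose null distribution
is obtained by resampling equally sized residue sets uniformly (without
replacement) from the structure.  The empirical p-value uses the add-one
correction p = (1 + #{null <= observed}) / (B + 1), so it is never exactly 0
and is uniform on its lattice under the null.  A colocalization variant tests
whether a second variant set B lies close to a fixed reference set A, using
the mean over B of the minimum distance to A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "StructureModel",
    "ClusterResult",
    "cluster_statistic",
    "bootstrap_pvalue",
    "colocalization_test",
]

ResidueId = tuple[str, int]  # (chain, residue_number)


def _mean_sorted(values: np.ndarray) -> float:
    # summation in sorted order so the statistic of a residue SET does not
    # depend on the order residues were drawn in (bit-stable resampling)
    return float(np.sort(values).sum() / len(values))


@dataclass
class StructureModel:
    """Cα trace of a protein structure with residue lookup.

    ``residue_ids`` are unique ``(chain, residue_number)`` pairs aligned with
    the rows of ``coords`` (N x 3, Ångström); ``amino_acids`` holds one-letter
    codes where known.
    """

    residue_ids: list[ResidueId]
    coords: np.ndarray
    amino_acids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residue_ids), 3):
            raise ValueError("coords must be (n_residues, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise ValueError("duplicate (chain, residue_number) identifiers")
        self._index = {rid: i for i, rid in enumerate(self.residue_ids)}

    def __len__(self) -> int:
        return len(self.residue_ids)

    def index_of(self, residues: Sequence[ResidueId | int], chain: Optional[str] = None) -> np.ndarray:
        """Row indices for residue ids; bare ints use ``chain`` (default: first).

        Raises ``KeyError`` listing every residue missing from the structure.
        """
        default_chain = chain or self.residue_ids[0][0]
        keys = [
            rid if isinstance(rid, tuple) else (default_chain, int(rid))
            for rid in residues
        ]
        missing = [k for k in keys if k not in self._index]
        if missing:
            raise KeyError(f"residues not in structure: {missing}")
        return np.array([self._index[k] for k in keys], dtype=int)

    @classmethod
    def from_pdb(
        cls,
        path: str,
        chain: Optional[str] = None,
        residue_offset: int = 0,
    ) -> "StructureModel":
        """Read Cα coordinates from PDB ATOM records.

        ``residue_offset`` is added to the file's residue numbers, absorbing
        isoform/crystal numbering differences between variant nomenclature
        and structure numbering.
        """
        from Bio.PDB import PDBParser
        from Bio.PDB.Polypeptide import protein_letters_3to1

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = PDBParser(QUIET=True).get_structure("s", path)[0]
        ids: list[ResidueId] = []
        coords: list[np.ndarray] = []
        aas: list[str] = []
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                if "CA" not in res:
                    continue
                hetflag, resseq, _ = res.id
                if hetflag.strip():
                    continue
                ids.append((ch.id, resseq + residue_offset))
                coords.append(res["CA"].coord)
                aas.append(protein_letters_3to1.get(res.get_resname().capitalize(), "X"))
        if not ids:
            raise ValueError(f"no Cα atoms found in {path}")
        return cls(ids, np.array(coords, dtype=float), aas)


@dataclass
class ClusterResult:
    observed_statistic: float
    n_bootstrap: int
    p_empirical: float
    seed: Optional[int]
    residues_used: list[ResidueId]
    null_statistics: Optional[np.ndarray] = None


def cluster_statistic(residues: Sequence[ResidueId | int], s: StructureModel, chain: Optional[str] = None) -> float:
    """Mean pairwise Euclidean Cα distance (Å) of a residue set."""
    if len(residues) < 2:
        raise ValueError("need at least 2 residues for a pairwise statistic")
    if len(set(residues)) != len(residues):
        raise ValueError(f"duplicate residue ids in {list(residues)}")
    idx = s.index_of(residues, chain=chain)
    return _mean_sorted(pdist(s.coords[idx]))


def _empirical_p(observed: float, null: np.ndarray) -> float:
    return (1 + int(np.sum(null <= observed))) / (len(null) + 1)


def bootstrap_pvalue(
    residues: Sequence[ResidueId | int],
    s: StructureModel,
    n_bootstrap: int = 10_000,
    seed: Optional[int] = None,
    chain: Optional[str] = None,
    keep_null: bool = False,
) -> ClusterResult:
    """Empirical clustering p-value by uniform resampling from the structure.

    Each replicate draws ``len(residues)`` distinct residues uniformly from
    all residues of the structure and recomputes the statistic; small
    observed values (tight clusters) yield small p.
    """
    if n_bootstrap < 100:
        raise ValueError(f"n_bootstrap must be >= 100, got {n_bootstrap}")
    if len(residues) > len(s):
        raise ValueError(
            f"cannot draw {len(residues)} residues from a structure of {len(s)}"
        )
    idx = s.index_of(residues, chain=chain)
    k = len(idx)
    observed = cluster_statistic(residues, s, chain=chain)
    rng = np.random.default_rng(seed)
    null = np.empty(n_bootstrap)
    n = len(s)
    for b in range(n_bootstrap):
        sample = rng.choice(n, size=k, replace=False)
        null[b] = _mean_sorted(pdist(s.coords[sample]))
    return ClusterResult(
        observed_statistic=observed,
        n_bootstrap=n_bootstrap,
        p_empirical=_empirical_p(observed, null),
        seed=seed,
        residues_used=[s.residue_ids[i] for i in idx],
        null_statistics=null if keep_null else None,
    )


def colocalization_test(
    set_a: Sequence[ResidueId | int],
    set_b: Sequence[ResidueId | int],
    s: StructureModel,
    n_bootstrap: int = 10_000,
    seed: Optional[int] = None,
    chain: Optional[str] = None,
    keep_null: bool = False,
) -> ClusterResult:
    """Test whether set B lies unusually close to a fixed reference set A.

    Statistic: mean over residues of B of the minimum Cα distance to A.
    Null: B's positions are resampled uniformly (without replacement) from
    the structure's residues outside A, with A held fixed.
    """
    idx_a = s.index_of(set_a, chain=chain)
    idx_b = s.index_of(set_b, chain=chain)
    if not len(idx_a) or not len(idx_b):
        raise ValueError("both residue sets must be non-empty")
    if set(idx_a) & set(idx_b):
        raise ValueError("residue sets must be disjoint")
    if n_bootstrap < 100:
        raise ValueError(f"n_bootstrap must be >= 100, got {n_bootstrap}")
    coords_a = s.coords[idx_a]

    def stat(idx_set: np.ndarray) -> float:
        return _mean_sorted(cdist(s.coords[idx_set], coords_a).min(axis=1))

    observed = stat(idx_b)
    pool = np.setdiff1d(np.arange(len(s)), idx_a)
    k = len(idx_b)
    if k > len(pool):
        raise ValueError(f"cannot draw {k} residues from {len(pool)} outside A")
    rng = np.random.default_rng(seed)
    null = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sample = rng.choice(pool, size=k, replace=False)
        null[b] = stat(sample)
    return ClusterResult(
        observed_statistic=observed,
        n_bootstrap=n_bootstrap,
        p_empirical=_empirical_p(observed, null),
        seed=seed,
        residues_used=[s.residue_ids[i] for i in idx_b],
        null_statistics=null if keep_null else None,
    )
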