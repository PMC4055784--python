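"""Chemical-space comparison of phytochemicals, drugs and metabolites.

Each molecule is described by 1027 columns: a 1024-bit circular fingerprint
plus molecular weight (MW), topological polar surface area (TPSA) and the
computed octanol/water partition coefficient (SlogP).  Columns are scaled to
mean 0 and standard deviation 1 jointly across all compound groups, pairwise
Euclidean distances are taken, and the configuration is embedded in two
dimensions by classical (Torgerson) multidimensional scaling — the
eigendecomposition of the double-centered matrix -D²/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

N_FP_BITS = 1024
DESCRIPTOR_COLUMNS = 3  # MW, TPSA, SlogP
N_COLUMNS = N_FP_BITS + DESCRIPTOR_COLUMNS  # 1027


@dataclass
class EmbeddingResult:
    """Classical-MDS embedding: per-row coordinates, the (non-increasing)
    eigenvalue spectrum of the centered matrix, and the fraction of total
    positive eigenvalue mass NOT captured by the kept axes (a stress
    proxy in [0, 1])."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    stress_proxy: float


def assemble_descriptor_matrix(compound_table: pd.DataFrame,
                               n_bits: int = N_FP_BITS) -> pd.DataFrame:
    """Expand a compound table into the dense row-per-molecule descriptor
    matrix: ``n_bits`` fingerprint columns then mw, tpsa, slogp.

    The ``fingerprint`` column holds comma-joined on-bit positions; the
    ``group`` column (phytochemical / drug / anticancer-drug /
    colon-metabolite), when present, is preserved as a row metadata index
    level, never as a feature.
    """
    from phytonet.io import decode_fingerprint

    n = len(compound_table)
    fp = np.zeros((n, n_bits), dtype=float)
    for i, text in enumerate(compound_table["fingerprint"].astype(str)):
        bits = list(decode_fingerprint(text))
        if bits and max(bits) >= n_bits:
            raise ValueError(
                f"fingerprint bit {max(bits)} out of range for {n_bits} bits")
        fp[i, bits] = 1.0
    cols = [f"fp_{i}" for i in range(n_bits)] + ["mw", "tpsa", "slogp"]
    data = np.column_stack([
        fp,
        compound_table["mw"].to_numpy(float),
        compound_table["tpsa"].to_numpy(float),
        compound_table["slogp"].to_numpy(float),
    ])
    if "group" in compound_table.columns:
        index = pd.MultiIndex.from_arrays(
            [compound_table["compound_id"], compound_table["group"]],
            names=["compound_id", "group"])
    else:
        index = pd.Index(compound_table["compound_id"], name="compound_id")
    matrix = pd.DataFrame(data, index=index, columns=cols)
    if matrix.isna().any().any():
        raise ValueError("descriptor matrix contains missing values")
    return matrix


def standardize_columns(matrix: pd.DataFrame | np.ndarray
                        ) -> pd.DataFrame | np.ndarray:
    """Scale each column to mean 0 and sample (n-1) standard deviation 1.

    Constant columns — e.g. a fingerprint bit set in no molecule — become
    all zeros rather than being dropped, preserving the column count.
    """
    values = np.asarray(matrix, dtype=float)
    mean = values.mean(axis=0)
    centered = values - mean
    if values.shape[0] > 1:
        sd = values.std(axis=0, ddof=1)
    else:
        sd = np.zeros(values.shape[1])
    out = np.divide(centered, sd, out=np.zeros_like(centered),
                    where=sd > 0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def euclidean_distances(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Full symmetric matrix of pairwise Euclidean distances between rows."""
    values = np.asarray(matrix, dtype=float)
    return squareform(pdist(values, metric="euclidean"))


def classical_mds(d: np.ndarray, k: int = 2) -> EmbeddingResult:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    B = -½ J D² J with J the centering matrix; coordinates are the top-``k``
    eigenvectors scaled by the square roots of their (non-negative)
    eigenvalues.  Negative eigenvalues — a non-Euclidean D — are truncated
    to zero; if fewer than ``k`` positive eigenvalues exist the remaining
    coordinates are zero-filled with a warning.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    d2 = d ** 2
    # double centering without materializing J
    row_mean = d2.mean(axis=1, keepdims=True)
    col_mean = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    b = -0.5 * (d2 - row_mean - col_mean + grand)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    positive = eigvals > 1e-8 * max(1.0, abs(eigvals[0]))
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); zero-filling the "
            f"remaining {k - n_pos} coordinate(s)", stacklevel=2)
    coords = np.zeros((n, k))
    use = min(k, n_pos)
    if use:
        coords[:, :use] = eigvecs[:, :use] * np.sqrt(eigvals[:use])
    pos_mass = float(eigvals[positive].sum())
    kept = float(eigvals[:use].sum()) if use else 0.0
    stress = 0.0 if pos_mass == 0 else 1.0 - kept / pos_mass
    return EmbeddingResult(coordinates=coords, eigenvalues=eigvals,
                           stress_proxy=stress)


def embed_compounds(compound_table: pd.DataFrame, k: int = 2
                    ) -> pd.DataFrame:
    """End-to-end chemical-space embedding of a compound table.

    Assembles the 1027-column descriptor matrix, standardizes jointly across
    groups, computes Euclidean distances and runs classical MDS.  Returns a
    tidy frame (compound_id, group, x, y) ready for plotting.
    """
    matrix = assemble_descriptor_matrix(compound_table)
    scaled = standardize_columns(matrix)
    dist = euclidean_distances(scaled)
    result = classical_mds(dist, k=k)
    out = pd.DataFrame(result.coordinates,
                       columns=[f"axis_{i + 1}" for i in range(k)])
    out.insert(0, "compound_id", compound_table["compound_id"].to_numpy())
    group = (compound_table["group"] if "group" in compound_table.columns
             else pd.Series(["compound"] * len(compound_table)))
    out.insert(1, "group", group.to_numpy())
    return out


def descriptors_from_smiles(smiles: str, n_bits: int = N_FP_BITS
                            ) -> tuple[frozenset[int], float, float, float]:
    """Compute (fingerprint on-bits, MW, TPSA, SlogP) from a SMILES string.

    Requires RDKit (optional dependency); the rest of the package accepts
    precomputed descriptors and never imports it.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "SMILES ingestion requires the optional rdkit dependency") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = rdMolDescriptors.GetMorganFingerprintAsBitVect(mol, radius=2,
                                                        nBits=n_bits)
    bits = frozenset(fp.GetOnBits())
    return (bits, Descriptors.MolWt(mol),
            rdMolDescriptors.CalcTPSA(mol), Crippen.MolLogP(mol))
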