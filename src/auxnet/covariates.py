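"""Sequence-dissimilarity covariate matrices in PHYLIP square format.

Evolutionary distances between the dimerisation sub-domains (DIII, DIV,
or their concatenation DIII/IV) are computed upstream with standard
phylogenetics tools (multiple alignment, conserved-block detection, and
a substitution-model distance such as PAM via PROTDIST); this module
only consumes their square-matrix output and aligns it to the protein
roster so the distances can enter the regression block models as edge
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .y2h import Roster

__all__ = [
    "CovariateSet",
    "read_phylip_square",
    "write_phylip_square",
    "align_covariates",
]


@dataclass
class CovariateSet:
    """Named symmetric distance matrices aligned to the roster.

    ``matrices`` has shape (d, n, n) with zero diagonals; row/column
    order equals roster order.
    """

    names: list[str]
    matrices: np.ndarray
    roster: Roster

    def __post_init__(self) -> None:
        n = len(self.roster)
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim == 2:
            m = m[None]
        if m.shape != (len(self.names), n, n):
            raise ValueError("matrices must be (d, n, n) matching names and roster")
        if not np.allclose(m, np.swapaxes(m, 1, 2)):
            raise ValueError("covariate matrices must be symmetric")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrices = m

    @property
    def d(self) -> int:
        return len(self.names)


def read_phylip_square(path) -> tuple[list[str], np.ndarray]:
    """Parse a PHYLIP square distance matrix.

    Format: first line holds the taxon count, then one row per taxon
    (name followed by the distances, possibly wrapped over several
    lines).  Names are whitespace-delimited, so long names are accepted.
    The matrix is symmetrized by averaging; asymmetries beyond 1e-8 are
    reported via ``ValueError`` only when the payload is not square.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError("empty PHYLIP file")
    try:
        n = int(tokens[0])
    except ValueError:
        raise ValueError(f"expected taxon count on first line, got {tokens[0]!r}")
    pos = 1
    labels: list[str] = []
    matrix = np.zeros((n, n))
    for i in range(n):
        if pos >= len(tokens):
            raise ValueError(f"taxon count mismatch: expected {n} rows, got {i}")
        labels.append(tokens[pos])
        pos += 1
        row = tokens[pos:pos + n]
        if len(row) < n:
            raise ValueError(f"non-square payload: row {labels[-1]!r} has "
                             f"{len(row)} of {n} values")
        try:
            matrix[i] = [float(v) for v in row]
        except ValueError as exc:
            raise ValueError(f"non-numeric value in row {labels[-1]!r}: {exc}")
        pos += n
    if pos != len(tokens):
        raise ValueError("trailing tokens after last row (taxon count mismatch?)")
    return labels, (matrix + matrix.T) / 2.0


def write_phylip_square(path, labels: list[str], matrix: np.ndarray,
                        values_per_line: int | None = None) -> None:
    """Write a labelled square matrix in PHYLIP format.

    ``values_per_line`` wraps rows (the classic dialect); ``None`` writes
    each row on a single line.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape must match labels")
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for label, row in zip(labels, matrix):
            vals = [f"{v:.6f}" for v in row]
            if values_per_line is None:
                fh.write(f"{label}  " + " ".join(vals) + "\n")
            else:
                fh.write(f"{label}  " + " ".join(vals[:values_per_line]) + "\n")
                for start in range(values_per_line, n, values_per_line):
                    fh.write("  " + " ".join(vals[start:start + values_per_line]) + "\n")


def align_covariates(matrices, roster: Roster) -> CovariateSet:
    """Subset and reorder labelled matrices to the roster.

    ``matrices`` maps a covariate name to a ``(labels, matrix)`` pair as
    returned by :func:`read_phylip_square`.  Every roster protein must be
    present in every matrix; a missing protein raises ``KeyError`` naming
    it.  Proteins lacking the dimerisation domain must have been excluded
    from the roster upstream.
    """
    names = list(matrices)
    aligned = []
    for name in names:
        labels, matrix = matrices[name]
        index = {lab: k for k, lab in enumerate(labels)}
        missing = [p for p in roster.proteins if p not in index]
        if missing:
            raise KeyError(f"covariate {name!r} lacks roster protein(s) {missing}")
        order = [index[p] for p in roster.proteins]
        sub = np.asarray(matrix, dtype=float)[np.ix_(order, order)].copy()
        np.fill_diagonal(sub, 0.0)
        aligned.append(sub)
    return CovariateSet(names=names, matrices=np.stack(aligned), roster=roster)
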