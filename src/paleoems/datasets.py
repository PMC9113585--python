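"""Access to the published Ediacaran incidence dataset.

The study data — a binary matrix of 86 Ediacaran localities x 124 taxa
with per-locality metadata — is published separately (figshare
10.6084/m9.figshare.13664105; Dryad https://doi.org/10.5061/dryad.1mh30)
and is not redistributed with this package.  Export the matrix and the
locality table to the two-CSV layout described in
:func:`paleoems.incidence.load_incidence` and point the loader at them.
"""

from __future__ import annotations

from pathlib import Path

from .incidence import IncidenceStudy, load_incidence

__all__ = ["EDIACARAN_DATA_DIR", "load_ediacaran"]

#: Default location searched for the study CSVs (relative to the repo root).
EDIACARAN_DATA_DIR = Path(__file__).resolve().parents[2] / "data"


def load_ediacaran(data_dir=None) -> IncidenceStudy:
    """Load the Ediacaran locality-by-taxa study data.

    Looks for ``ediacaran_matrix.csv`` and ``ediacaran_metadata.csv`` in
    ``data_dir`` (default: the repository's ``data/`` directory).
    """
    root = Path(data_dir) if data_dir is not None else EDIACARAN_DATA_DIR
    matrix = root / "ediacaran_matrix.csv"
    meta = root / "ediacaran_metadata.csv"
    if not matrix.exists() or not meta.exists():
        raise FileNotFoundError(
            "Ediacaran incidence dataset not found: place the published "
            "locality-by-taxa matrix as "
            f"{matrix} and the locality metadata as {meta} "
            "(sources: doi:10.6084/m9.figshare.13664105, "
            "doi:10.5061/dryad.1mh30)"
        )
    return load_incidence(matrix, meta)
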