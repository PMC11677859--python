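"""Core containers for omics abundance matrices and sample metadata.

An :class:`OmicsMatrix` wraps a feature-by-sample :class:`pandas.DataFrame`
whose ``NaN`` entries mark values missing because they fell below detection
(the missingness mask), together with a processing-state flag that enforces
the pipeline order raw -> normalized -> imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STATES = ("raw", "normalized", "imputed")
LAYERS = ("protein", "metabolite", "microbiome")

#: diagnosis labels used throughout: cognitively normal, mild cognitive
#: impairment, Alzheimer's disease
DIAGNOSES = ("CN", "MCI", "AD")


class StateError(RuntimeError):
    """Raised when an operation is applied to a matrix in the wrong state."""


@dataclass
class OmicsMatrix:
    """One omics layer: features x samples with an explicit missingness mask.

    Parameters
    ----------
    values
        Feature-by-sample abundances. ``NaN`` encodes a missing (masked)
        cell; the mask is therefore ``values.isna()``.
    state
        One of ``raw``, ``normalized``, ``imputed``. Raw values are strictly
        positive where observed; normalized/imputed values live on the log
        scale and are unitless.
    layer
        One of ``protein``, ``metabolite``, ``microbiome``.
    """

    values: pd.DataFrame
    state: str = "raw"
    layer: str = "protein"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index="feature_id", columns=None)
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.state == "imputed" and self.values.isna().any().any():
            raise ValueError("imputed matrix must have an empty missingness mask")
        if self.state == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) <= 0:
                i, j = np.argwhere(vals <= 0)[0]
                raise ValueError(
                    "raw abundances must be strictly positive where observed; "
                    f"feature {self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean mask, True where the cell is missing."""
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise StateError(
                f"operation requires state in {allowed}, matrix is {self.state!r}"
            )

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values.copy(), state=self.state, layer=self.layer, params=dict(self.params)
        )


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (missing cells empty) plus a JSON sidecar.

    The sidecar ``<path>.json`` records the processing state, layer and any
    parameters so the mask and provenance round-trip through disk.
    """
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="")
    sidecar = {"state": matrix.state, "layer": matrix.layer, "params": matrix.params}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path: str | Path) -> OmicsMatrix:
    """Read a TSV matrix written by :func:`write_matrix`."""
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="feature_id")
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    else:
        sidecar = {"state": "raw", "layer": "protein", "params": {}}
    return OmicsMatrix(
        values,
        state=sidecar.get("state", "raw"),
        layer=sidecar.get("layer", "protein"),
        params=sidecar.get("params", {}),
    )


def validate_metadata(metadata: pd.DataFrame) -> None:
    """Check a sample-metadata table: unique ids, known diagnosis labels."""
    if metadata.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    if "diagnosis" not in metadata.columns:
        raise ValueError("metadata must contain a 'diagnosis' column")
    bad = set(metadata["diagnosis"].unique()) - set(DIAGNOSES)
    if bad:
        raise ValueError(f"unknown diagnosis labels {sorted(bad)}; expected {DIAGNOSES}")


def diagnosis_codes(metadata: pd.DataFrame) -> pd.Series:
    """Ordinal disease-severity code: CN=0, MCI=1, AD=2."""
    return metadata["diagnosis"].map({d: i for i, d in enumerate(DIAGNOSES)}).astype(float)
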