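"""Core data containers shared by every pipeline stage.

The pipeline operates on probe-by-sample intensity matrices from two-group
bead-array experiments (labouring vs non-labouring myometrium, or any
two-condition bulk tissue design).  :class:`ExpressionMatrix` wraps the
intensity table together with the negative-control flags that drive
background correction and the detection floor; sample metadata travels as a
plain :class:`pandas.DataFrame` validated by :func:`check_metadata`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_LABOUR = "labour"
GROUP_NONLABOUR = "nonlabour"

#: Columns a sample-metadata table must carry (besides the sample_id index).
METADATA_COLUMNS = (
    "group",
    "parity",
    "bmi",
    "maternal_age",
    "gestational_weeks",
    "induction",
    "chip",
)


class ConfigurationError(ValueError):
    """A parameter or input value violates a stage's contract."""


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity matrix with negative-control flags.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
        Intensities must be finite; most stages additionally require them
        positive.
    is_control
        Boolean Series aligned to ``values.index`` flagging negative-control
        probes (no biological target; intensity is pure background).
    annotation
        Optional per-probe annotation (e.g. a ``gene_symbol`` column),
        indexed like ``values``.
    """

    values: pd.DataFrame
    is_control: pd.Series
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate probe ids in expression matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        self.is_control = self.is_control.reindex(v.index)
        if self.is_control.isna().any():
            raise ValueError("is_control flags missing for some probes")
        self.is_control = self.is_control.astype(bool)
        if self.annotation is not None:
            self.annotation = self.annotation.reindex(v.index)

    # -- convenience views -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def controls(self) -> pd.DataFrame:
        """Intensity sub-matrix of the negative-control probes."""
        return self.values.loc[self.is_control.to_numpy()]

    def regular(self) -> pd.DataFrame:
        """Intensity sub-matrix of the biological (non-control) probes."""
        return self.values.loc[~self.is_control.to_numpy()]

    def subset_probes(self, probes: pd.Index | list[str]) -> "ExpressionMatrix":
        ann = self.annotation.loc[probes] if self.annotation is not None else None
        return ExpressionMatrix(
            values=self.values.loc[probes].copy(),
            is_control=self.is_control.loc[probes].copy(),
            annotation=ann,
        )

    def subset_samples(self, samples: pd.Index | list[str]) -> "ExpressionMatrix":
        ann = self.annotation.copy() if self.annotation is not None else None
        return ExpressionMatrix(
            values=self.values.loc[:, list(samples)].copy(),
            is_control=self.is_control.copy(),
            annotation=ann,
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Same probes/flags/annotation, new intensity table."""
        return ExpressionMatrix(
            values=values,
            is_control=self.is_control.copy(),
            annotation=self.annotation.copy() if self.annotation is not None else None,
        )

    # -- TSV dialect -------------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, controls_path: str | Path | None = None) -> None:
        """Write the matrix (first column ``probe_id``) and, optionally, the
        companion single-column control-probe list."""
        out = self.values.copy()
        out.insert(0, "probe_id", out.index)
        out.to_csv(matrix_path, sep="\t", index=False)
        if controls_path is not None:
            ctrl = pd.DataFrame({"probe_id": self.probe_ids[self.is_control.to_numpy()]})
            ctrl.to_csv(controls_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        matrix_path: str | Path,
        controls_path: str | Path | None = None,
        annotation: pd.DataFrame | None = None,
    ) -> "ExpressionMatrix":
        tab = pd.read_csv(matrix_path, sep="\t")
        tab = tab.set_index("probe_id")
        if controls_path is not None:
            ctrl_ids = set(pd.read_csv(controls_path, sep="\t")["probe_id"].astype(str))
        else:
            ctrl_ids = set()
        flags = pd.Series([str(p) in ctrl_ids for p in tab.index], index=tab.index)
        return cls(values=tab, is_control=flags, annotation=annotation)


def check_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it indexed by sample_id."""
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    if md.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    missing = [c for c in ("group",) if c not in md.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    bad = set(md["group"]) - {GROUP_LABOUR, GROUP_NONLABOUR}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return md


def group_samples(metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Return (labouring sample ids, non-labouring sample ids)."""
    md = check_metadata(metadata)
    lab = list(md.index[md["group"] == GROUP_LABOUR])
    non = list(md.index[md["group"] == GROUP_NONLABOUR])
    return lab, non


def require_positive(name: str, value: float, strict: bool = True) -> None:
    """Raise :class:`ConfigurationError` naming ``name`` unless value is a
    finite (strictly) positive number."""
    if not np.isfinite(value):
        raise ConfigurationError(f"parameter {name!r} must be finite, got {value!r}")
    if strict and value <= 0:
        raise ConfigurationError(f"parameter {name!r} must be > 0, got {value!r}")
    if not strict and value < 0:
        raise ConfigurationError(f"parameter {name!r} must be >= 0, got {value!r}")
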