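"""Flattened competing-risks observations.

A :class:`CRSample` is the common currency of the estimation modules: one
row per cell with a positive event/censoring time, an integer cause code
(0 = right censored, 1..K = competing causes), a numeric covariate matrix,
and optional cluster / pedigree / generation labels used for
cluster-robust variance and kinship pairing.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CRSample"]


class CRSample:
    """Competing-risks observations ``(T, status, X, cluster)``.

    Parameters
    ----------
    time
        Event or censoring times, strictly positive (hours).
    status
        Integer cause codes; 0 marks right censoring, 1..K the competing
        causes.
    covariates
        Optional numeric covariate frame (one row per observation).
    cluster, pedigree, generation, ids
        Optional per-observation labels.  ``ids`` are cell identifiers
        retained so kin pairs can be joined back onto the sample.
    cause_map
        Mapping from fate label to cause code, recorded alongside the data.

    Rows with a missing required field are rejected at construction, never
    silently dropped.
    """

    def __init__(
        self,
        time: Sequence[float],
        status: Sequence[int],
        covariates: pd.DataFrame | Mapping[str, Sequence] | None = None,
        *,
        cluster: Sequence | None = None,
        pedigree: Sequence | None = None,
        generation: Sequence[int] | None = None,
        ids: Sequence[str] | None = None,
        censor_kind: Sequence[str] | None = None,
        cause_map: Mapping[str, int] | None = None,
    ) -> None:
        time = np.asarray(time, dtype=float)
        if time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        if time.size == 0:
            raise ValueError("empty sample")
        if np.any(~np.isfinite(time)):
            raise ValueError("non-finite or missing times are not allowed")
        if np.any(time <= 0):
            bad = np.nonzero(time <= 0)[0][:10]
            raise ValueError(f"times must be > 0; offending rows: {bad.tolist()}")

        status_arr = np.asarray(status)
        if status_arr.shape != time.shape:
            raise ValueError("status and time must have equal length")
        if not np.issubdtype(status_arr.dtype, np.integer):
            as_float = np.asarray(status, dtype=float)
            if np.any(~np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                raise ValueError("status must be integer cause codes")
            status_arr = as_float.astype(int)
        if np.any(status_arr < 0):
            raise ValueError("status codes must be >= 0 (0 = censored)")

        self.time = time
        self.status = status_arr.astype(int)
        if covariates is None:
            self.covariates = pd.DataFrame(index=pd.RangeIndex(time.size))
        else:
            cov = pd.DataFrame(covariates).reset_index(drop=True)
            if len(cov) != time.size:
                raise ValueError("covariates must have one row per observation")
            if cov.isna().any().any():
                raise ValueError("missing covariate values are not allowed")
            self.covariates = cov

        def _arr(x, name):
            if x is None:
                return None
            a = np.asarray(x)
            if a.shape != time.shape:
                raise ValueError(f"{name} must have one entry per observation")
            return a

        self.cluster = _arr(cluster, "cluster")
        self.pedigree = _arr(pedigree, "pedigree")
        self.generation = _arr(generation, "generation")
        self.ids = _arr(ids, "ids")
        #: censoring-fate label per censored row ("lost" vs
        #: "end_of_observation"); lets IPCW treat the individual and the
        #: shared censoring mechanisms separately
        self.censor_kind = _arr(censor_kind, "censor_kind")
        self.cause_map = dict(cause_map) if cause_map else None

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.time.size

    @property
    def causes(self) -> np.ndarray:
        """Sorted distinct non-zero cause codes present in the sample."""
        c = np.unique(self.status)
        return c[c > 0]

    @property
    def n_events(self) -> int:
        return int(np.sum(self.status > 0))

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        *,
        time_col: str = "time",
        status_col: str = "status",
        covariate_cols: Sequence[str] | None = None,
        cluster_col: str | None = None,
        pedigree_col: str | None = None,
        generation_col: str | None = None,
        id_col: str | None = None,
        cause_map: Mapping[str, int] | None = None,
    ) -> "CRSample":
        cov = frame[list(covariate_cols)] if covariate_cols else None
        return cls(
            frame[time_col].to_numpy(),
            frame[status_col].to_numpy(),
            cov,
            cluster=frame[cluster_col].to_numpy() if cluster_col else None,
            pedigree=frame[pedigree_col].to_numpy() if pedigree_col else None,
            generation=frame[generation_col].to_numpy() if generation_col else None,
            ids=frame[id_col].to_numpy() if id_col else None,
            cause_map=cause_map,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.time, "status": self.status})
        for name, arr in (
            ("cluster", self.cluster),
            ("pedigree", self.pedigree),
            ("generation", self.generation),
            ("cell_id", self.ids),
        ):
            if arr is not None:
                out[name] = arr
        for col in self.covariates.columns:
            out[col] = self.covariates[col].to_numpy()
        return out

    def subset(self, mask: np.ndarray) -> "CRSample":
        mask = np.asarray(mask, dtype=bool)
        return CRSample(
            self.time[mask],
            self.status[mask],
            self.covariates.loc[mask].reset_index(drop=True)
            if not self.covariates.empty
            else None,
            cluster=self.cluster[mask] if self.cluster is not None else None,
            pedigree=self.pedigree[mask] if self.pedigree is not None else None,
            generation=self.generation[mask] if self.generation is not None else None,
            ids=self.ids[mask] if self.ids is not None else None,
            censor_kind=(self.censor_kind[mask]
                         if self.censor_kind is not None else None),
            cause_map=self.cause_map,
        )

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        k = self.causes.size
        cens = int(np.sum(self.status == 0))
        return f"<CRSample n={self.n} causes={k} censored={cens}>"
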