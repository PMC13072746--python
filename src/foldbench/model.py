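"""Chain-length baseline model for protein folding rates.

The model is the two-parameter log-linear law

    ln(k_f) = a0 + a1 * ln(L)

with ``L`` the number of residues and ``k_f`` the folding rate in s^-1.
Despite its simplicity it is competitive, on external protein sets, with
multivariate sequence-descriptor predictors — which is the scientific point
this package exists to make quantitative.

Usage follows the model/results idiom::

    model = LengthRateModel(dataset)
    res = model.fit()
    res.params          # (a0, a1)
    res.predict(100)    # ln k_f at L = 100
    res.loo()           # leave-one-out cross-validation report
    print(res.summary())

The fit is ordinary least squares in (ln L, ln k_f), computed in closed form
from centred moments — a deliberately transparent two-parameter solve whose
correctness is cross-checked in the test suite against a normal-equations
solver.  Duplicated proteins count as independent observations, matching how
the published compilations use them.

The fitted results carry a *minimal applicability domain*: the inclusive
training length range [L_min, L_max].  Predictions outside it are still
returned (the law is defined for all L >= 1) but :meth:`LengthRateResults.in_domain`
lets callers flag them, in the spirit of QSAR-style applicability domains.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .datasets import ProteinDataset


class DegenerateDesignError(ValueError):
    """All training lengths equal: the slope on ln(L) is unidentifiable."""


class InsufficientDataError(ValueError):
    """Fewer than 3 observations."""


def _as_arrays(train: ProteinDataset) -> tuple[np.ndarray, np.ndarray]:
    return train.lengths(), train.ln_kf()


class LengthRateModel:
    """OLS model ln(k_f) = a0 + a1*ln(L) over a protein dataset.

    Parameters
    ----------
    data
        A :class:`~foldbench.datasets.ProteinDataset`, or anything with
        ``length`` and ``ln_kf`` columns via :meth:`from_dataframe`.
    """

    def __init__(self, data: ProteinDataset):
        self.data = data
        self.lengths, self.ln_kf = _as_arrays(data)
        if len(self.lengths) < 3:
            raise InsufficientDataError(
                f"need >= 3 observations, got {len(self.lengths)}"
            )
        if np.ptp(self.lengths) == 0:
            raise DegenerateDesignError("all training lengths are equal")

    @classmethod
    def from_dataframe(cls, df, name: str = "dataframe") -> "LengthRateModel":
        """Build from a DataFrame with ``length`` (or ``sequence``) and ``ln_kf``."""
        from .datasets import ProteinRecord

        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            rowd = row._asdict()
            records.append(
                ProteinRecord(
                    pdb_id=str(rowd.get("pdb_id", f"R{i:03d}")),
                    ln_kf=float(rowd["ln_kf"]),
                    sequence=rowd.get("sequence") or None,
                    length=int(rowd["length"]) if rowd.get("length") else None,
                    source=name,
                )
            )
        return cls(ProteinDataset(name=name, records=records))

    def fit(self) -> "LengthRateResults":
        """Closed-form OLS via centred moments of (ln L, ln k_f)."""
        x = np.log(self.lengths)
        y = self.ln_kf
        n = len(x)
        xbar = x.mean()
        ybar = y.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        sxy = float(np.sum((x - xbar) * (y - ybar)))
        a1 = sxy / sxx
        a0 = ybar - a1 * xbar
        resid = y - (a0 + a1 * x)
        # standard errors from the usual unbiased residual variance (df = n-2)
        s2 = float(np.sum(resid**2)) / (n - 2) if n > 2 else float("nan")
        se_a1 = math.sqrt(s2 / sxx)
        se_a0 = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
        return LengthRateResults(
            a0=a0,
            a1=a1,
            n_train=n,
            training_name=self.data.name,
            domain_L=(int(self.lengths.min()), int(self.lengths.max())),
            bse=(se_a0, se_a1),
            resid=resid,
            model=self,
        )


@dataclass
class LengthRateResults:
    """Fitted ln(k_f) = a0 + a1*ln(L) with training metadata.

    Can also be constructed from serialised coefficients (:meth:`from_params`
    / :meth:`from_json`), in which case the residual-level attributes are
    absent but prediction and domain checks work.
    """

    a0: float
    a1: float
    n_train: int
    training_name: str
    domain_L: tuple[int, int]
    bse: Optional[tuple[float, float]] = None
    resid: Optional[np.ndarray] = None
    model: Optional[LengthRateModel] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a0) and math.isfinite(self.a1)):
            raise ValueError("coefficients must be finite")
        if self.n_train < 3:
            raise InsufficientDataError("n_train must be >= 3")
        lo, hi = self.domain_L
        if lo > hi:
            raise ValueError("invalid length domain")

    # -- core law ---------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        return np.array([self.a0, self.a1])

    def predict(self, L) -> Union[float, np.ndarray]:
        """ln(k_f) at length(s) *L* (strictly decreasing in L when a1 < 0)."""
        L_arr = np.asarray(L, dtype=float)
        if np.any(L_arr < 1):
            raise ValueError("L must be >= 1")
        out = self.a0 + self.a1 * np.log(L_arr)
        return float(out) if np.isscalar(L) or out.ndim == 0 else out

    def in_domain(self, L: int) -> str:
        """Classify *L* against the training range: inside / outside-low / outside-high."""
        lo, hi = self.domain_L
        if L < lo:
            return "outside-low"
        if L > hi:
            return "outside-high"
        return "inside"

    # -- diagnostics ------------------------------------------------------
    @property
    def fittedvalues(self) -> np.ndarray:
        if self.model is None:
            raise ValueError("results were loaded from parameters; no training data")
        return self.a0 + self.a1 * np.log(self.model.lengths)

    @property
    def rmse_fit(self) -> float:
        if self.resid is None:
            raise ValueError("results were loaded from parameters; no residuals")
        return float(np.sqrt(np.mean(self.resid**2)))

    def evaluate_fit(self):
        from .validation import evaluate_fit

        if self.model is None:
            raise ValueError("results were loaded from parameters; no training data")
        return evaluate_fit(self, self.model.data)

    def loo(self):
        """Leave-one-out cross-validation report (refits n models)."""
        from .validation import loo_cv

        if self.model is None:
            raise ValueError("results were loaded from parameters; no training data")
        return loo_cv(self.model.data)

    def evaluate_external(self, test: ProteinDataset, min_length: Optional[int] = None):
        from .validation import evaluate_external

        return evaluate_external(self, test, min_length=min_length)

    def to_rate_law(self):
        from .theory import to_rate_law

        return to_rate_law(self)

    # -- presentation / serialisation -------------------------------------
    def equation(self) -> str:
        sign = "−" if self.a1 < 0 else "+"
        return f"ln(k_f) = {self.a0:.3f} {sign} {abs(self.a1):.3f}·ln(L)"

    def summary(self) -> str:
        lines = [
            "Chain-length folding-rate model (OLS)",
            "=" * 46,
            f"training set : {self.training_name} (n = {self.n_train})",
            f"length domain: [{self.domain_L[0]}, {self.domain_L[1]}] residues",
            f"model        : {self.equation()}",
        ]
        if self.bse is not None:
            lines.append(
                f"std. errors  : a0 {self.bse[0]:.3f}   a1 {self.bse[1]:.3f}"
            )
        if self.resid is not None:
            lines.append(f"fit RMSE     : {self.rmse_fit:.2f}  (ln k_f units)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a1": self.a1,
            "n_train": self.n_train,
            "training_name": self.training_name,
            "L_min": self.domain_L[0],
            "L_max": self.domain_L[1],
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_params(
        cls,
        a0: float,
        a1: float,
        n_train: int = 3,
        training_name: str = "external",
        domain_L: tuple[int, int] = (1, 10**6),
    ) -> "LengthRateResults":
        return cls(
            a0=float(a0),
            a1=float(a1),
            n_train=int(n_train),
            training_name=training_name,
            domain_L=(int(domain_L[0]), int(domain_L[1])),
        )

    @classmethod
    def from_json(cls, path) -> "LengthRateResults":
        d = json.loads(Path(path).read_text())
        return cls.from_params(
            d["a0"],
            d["a1"],
            n_train=d.get("n_train", 3),
            training_name=d.get("training_name", "external"),
            domain_L=(d.get("L_min", 1), d.get("L_max", 10**6)),
        )


def fit_loglinear(train: ProteinDataset) -> LengthRateResults:
    """Fit the ln(k_f) = a0 + a1*ln(L) baseline to *train* (convenience)."""
    return LengthRateModel(train).fit()
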