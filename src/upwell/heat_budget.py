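"""Mixed-layer heat-budget bookkeeping.

Terms (all degC/day): ``tot`` the total mixed-layer temperature tendency,
``xadv``/``yadv``/``zadv`` the zonal/meridional/vertical advection,
``ldf`` lateral diffusion, ``zdf`` vertical diffusion/mixing, ``qnet``
the air-sea heat-flux storage (Qns + Qsr*(1 - f)) / (rho0 * cp * H).

The flux-storage anomaly splits into a flux-anomaly part acting on the
climatological mixed-layer depth (Q' term) and a depth-anomaly part
acting on the climatological heating (H' term, entering with a minus
sign); the residual is defined as the exact remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .anomalies import _climatology_array, anomaly_series
from .errors import AlignmentError, ConfigError, DataError

RHO0 = 1027.0  # kg m-3
CP = 4000.0  # J kg-1 K-1
SECONDS_PER_DAY = 86_400.0

RHS_TERMS = ("xadv", "yadv", "zadv", "ldf", "zdf", "qnet")


@dataclass
class HeatBudgetTerms:
    """Aligned budget term series in degC/day."""

    tot: pd.Series
    xadv: pd.Series
    yadv: pd.Series
    zadv: pd.Series
    ldf: pd.Series
    zdf: pd.Series
    qnet: pd.Series

    def __post_init__(self) -> None:
        idx = self.tot.index
        for name in RHS_TERMS:
            if not getattr(self, name).index.equals(idx):
                raise AlignmentError(f"term {name!r} not on the tot time axis")

    def rhs_sum(self) -> pd.Series:
        out = sum(getattr(self, name) for name in RHS_TERMS)
        out.name = "rhs_sum"
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tot": self.tot, **{n: getattr(self, n) for n in RHS_TERMS}}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HeatBudgetTerms":
        missing = [c for c in ("tot",) + RHS_TERMS if c not in df.columns]
        if missing:
            raise DataError(f"budget table missing columns {missing}")
        return cls(**{c: df[c] for c in ("tot",) + RHS_TERMS})


@dataclass
class AirSeaFlux:
    """Surface flux inputs for the storage term (series or scalars)."""

    qns: pd.Series  # non-solar flux, W m-2
    qsr: pd.Series  # solar flux, W m-2
    f_penetration: float | pd.Series  # shortwave fraction through the ML base
    mld: pd.Series  # mixed-layer depth, m
    rho0: float = RHO0
    cp: float = CP


def qnet_storage(flux: AirSeaFlux) -> pd.Series:
    """(Qns + Qsr (1 - f)) / (rho0 cp H), converted to degC/day."""
    mld = np.asarray(flux.mld, dtype=float)
    if np.any(mld <= 0):
        raise DataError("mixed-layer depth must be positive")
    f = flux.f_penetration
    fv = np.asarray(f, dtype=float)
    if np.any((fv < 0) | (fv > 1)):
        raise ConfigError("penetration fraction must lie in [0, 1]")
    total = flux.qns + flux.qsr * (1.0 - f)
    out = total / (flux.rho0 * flux.cp * flux.mld) * SECONDS_PER_DAY
    out.name = "qnet"
    return out


def closure_residual(terms: HeatBudgetTerms) -> pd.Series:
    """tot minus the sum of the six right-hand-side terms."""
    out = terms.tot - terms.rhs_sum()
    out.name = "closure_residual"
    return out


@dataclass
class QnetDecomposition:
    """Split of the flux-storage anomaly; the identity
    ``qnet_ano = q_term - h_term + residual`` holds exactly."""

    q_term: pd.Series
    h_term: pd.Series
    residual: pd.Series
    qnet_ano: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qnet_ano": self.qnet_ano,
                "q_term": self.q_term,
                "h_term": self.h_term,
                "residual": self.residual,
            }
        )


def _monthly_clim_series(series: pd.Series) -> pd.Series:
    """Calendar-month climatology broadcast back onto the series index."""
    months = pd.DatetimeIndex(series.index).month.to_numpy()
    clim = _climatology_array(series.to_numpy(dtype=float)[:, None], months)[:, 0]
    return pd.Series(clim[months - 1], index=series.index)


def decompose_qnet(
    Q: pd.Series,
    H: pd.Series,
    rho0: float = RHO0,
    cp: float = CP,
) -> QnetDecomposition:
    """Decompose the storage anomaly into Q' and H' contributions.

    ``Q`` is the total absorbed flux (W m-2), ``H`` the mixed-layer
    depth (m).  Anomalies are detrended + deseasonalized; climatologies
    are monthly (12-valued).  Output series are in degC/day.
    """
    if not Q.index.equals(H.index):
        raise AlignmentError("Q and H must share a time axis")
    if np.any(np.asarray(H, dtype=float) <= 0):
        raise DataError("mixed-layer depth must be positive")
    h_clim = _monthly_clim_series(H)
    if np.any(h_clim.to_numpy() <= 0):
        raise DataError("degenerate mixed-layer depth climatology")
    q_clim = _monthly_clim_series(Q)

    qnet = Q / (rho0 * cp * H) * SECONDS_PER_DAY
    qnet_ano = anomaly_series(qnet)
    dQ = anomaly_series(Q)
    dH = anomaly_series(H)

    q_term = dQ / (rho0 * cp * h_clim) * SECONDS_PER_DAY
    h_term = dH * q_clim / (rho0 * cp * h_clim**2) * SECONDS_PER_DAY
    residual = qnet_ano - q_term + h_term
    return QnetDecomposition(
        q_term=q_term.rename("q_term"),
        h_term=h_term.rename("h_term"),
        residual=residual.rename("residual"),
        qnet_ano=qnet_ano.rename("qnet_ano"),
    )


def contribution_percentages(term_anomalies: dict[str, float]) -> pd.DataFrame:
    """Share of each same-signed term in the net warming (or cooling).

    Positive terms are expressed as percentages of the summed positive
    anomalies (the anomalous warming); negative terms keep their sign and
    get no percentage.  If every term is <= 0 the accounting flips to the
    cooling side (percentages over negative terms).
    """
    items = {k: float(v) for k, v in term_anomalies.items()}
    if not items:
        raise ConfigError("no terms supplied")
    pos = {k: v for k, v in items.items() if v > 0}
    warming = bool(pos)
    side = pos if warming else {k: v for k, v in items.items() if v < 0}
    if not side:
        raise DataError("all terms are zero; contribution undefined")
    total = sum(side.values())
    rows = []
    for k, v in items.items():
        in_side = (v > 0) if warming else (v < 0)
        rows.append(
            {
                "term": k,
                "value": v,
                "percent": 100.0 * v / total if in_side else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mode"] = "warming" if warming else "cooling"
    return df
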