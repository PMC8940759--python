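"""CSV / config / results serialisation.

Concentration series travel as CSV with columns ``time_h, conc_mg_L``;
configuration as JSON or YAML; high-precision values serialise as decimal
strings (65-digit results do not survive a binary float round trip).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd
import yaml

import mpmath as mp

from .errors import DomainError
from .params import ConcentrationModel, ConcentrationSeries, DoseRegimen
from .policy import PrecisionPolicy

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "load_config",
    "dump_results_json",
    "multidose_trajectory",
]


def read_series_csv(path: Union[str, Path], subject_id: str = "") -> ConcentrationSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_h", "conc_mg_L"):
        if col not in df.columns:
            raise DomainError(f"CSV must have a '{col}' column (header required)")
    return ConcentrationSeries(
        times=df["time_h"].to_numpy(float),
        concs=df["conc_mg_L"].to_numpy(float),
        subject_id=subject_id or str(path),
    )


def write_series_csv(series: ConcentrationSeries, path: Union[str, Path]) -> None:
    # repr-roundtrip float formatting so write->read is exact
    df = pd.DataFrame({"time_h": series.times, "conc_mg_L": series.concs})
    df.to_csv(path, index=False, float_format="%.17g")


def load_config(path: Union[str, Path]) -> dict:
    """JSON or YAML config by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _mpf_str(x: mp.mpf) -> str:
    """Decimal string carrying the full precision stored in the mpf itself
    (independent of the ambient mpmath context)."""
    from mpmath.libmp import prec_to_dps

    bitcount = x._mpf_[3] if len(x._mpf_) == 4 else 53
    return mp.nstr(x, max(17, prec_to_dps(bitcount) + 3))


def _jsonable(x: Any) -> Any:
    if isinstance(x, mp.mpf):
        return _mpf_str(x)
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def dump_results_json(obj: Any, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def multidose_trajectory(
    model: ConcentrationModel,
    regimen: DoseRegimen,
    times: np.ndarray,
    policy: PrecisionPolicy = PrecisionPolicy(target_digits=20, guard_digits=5),
) -> pd.DataFrame:
    """Sampled superposed concentration and body-burden trajectory,
    suitable for CSV export or plotting."""
    from .multidose import conc_multidose, doses_retained

    rows = [
        (
            float(t),
            float(conc_multidose(t, model, regimen, policy)),
            float(doses_retained(t, model.params, regimen, policy)),
        )
        for t in np.asarray(times, dtype=float)
    ]
    return pd.DataFrame(rows, columns=["t_h", "conc_mg_L", "doses_retained"])
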