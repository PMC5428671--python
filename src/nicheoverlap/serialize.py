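"""Flatten result objects into JSON-serializable structures."""

from __future__ import annotations

from typing import Any

import numpy as np

from .comparison import AnovaTable, PairRecord, SpeciesRecord
from .cooccurrence import CScoreResult
from .nullmodels import NullModelResult
from .overlap import OverlapResult


def to_jsonable(obj: Any) -> Any:
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, OverlapResult):
        return {
            "label": obj.label,
            "species_ids": list(obj.species_ids),
            "O": obj.O.tolist(),
            "O_sp": obj.O_sp.tolist(),
            "mean_overall": obj.mean_overall,
        }
    if isinstance(obj, CScoreResult):
        return {
            "label": obj.label,
            "species_ids": list(obj.species_ids),
            "pairwise_c": obj.pairwise_c.tolist(),
            "mean_c": obj.mean_c,
        }
    if isinstance(obj, NullModelResult):
        return obj.as_dict()
    if isinstance(obj, AnovaTable):
        return {
            "rows": obj.to_frame().to_dict(orient="records"),
            "gg_epsilon": obj.gg_epsilon,
        }
    if isinstance(obj, PairRecord):
        return {
            "species_a": obj.species_a,
            "species_b": obj.species_b,
            "pair_type": obj.pair_type,
            "values": dict(obj.values),
        }
    if isinstance(obj, SpeciesRecord):
        return {
            "species_id": obj.species_id,
            "specialisation": obj.specialisation,
            "values": dict(obj.values),
        }
    if isinstance(obj, dict):
        return {_key(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    raise TypeError(f"cannot serialize {type(obj)!r}")


def _key(k: Any) -> str:
    if isinstance(k, tuple):
        return ":".join(str(x) for x in k)
    return str(k)
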