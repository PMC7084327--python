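"""ADME screening of herb components.

Candidate compounds from a medicinal herb are triaged with the
pharmacokinetic filters customary in network pharmacology before any
network is built:

* oral bioavailability (OB, percent of an oral dose reaching circulation),
* Caco-2 permeability (log-scale intestinal epithelial permeability),
* drug-likeness (DL, a Tanimoto similarity between a compound's descriptor
  vector and the average descriptor profile of approved drugs),
* a binary gastrointestinal (GI) absorption class (High/Low), and
* Lipinski's rule of five.

Components failing the strict filter can be added back through an explicit
whitelist when prior pharmacology justifies keeping them; the screen report
records both routes of retention separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentRecord",
    "ScreenThresholds",
    "ScreenReport",
    "lipinski_check",
    "tanimoto_dl",
    "adme_screen",
    "read_components",
]


@dataclass(frozen=True)
class ComponentRecord:
    """One herb component with its physicochemical/pharmacokinetic descriptors.

    ``RBN`` (rotatable bond number) is optional: public property tables often
    omit it, in which case the corresponding Lipinski sub-condition is skipped.
    """

    id: str
    name: str
    MW: float
    AlogP: float
    nHdon: int
    nHacc: int
    TPSA: float
    OB: float
    Caco2: float
    DL: float
    GI: str
    RBN: Optional[int] = None

    def __post_init__(self) -> None:
        if not str(self.id).strip():
            raise ValueError("component id must be non-empty")
        for attr in ("MW", "AlogP", "TPSA", "OB", "Caco2", "DL"):
            v = getattr(self, attr)
            if not math.isfinite(float(v)):
                raise ValueError(f"{self.id}: {attr} is not finite")
        if self.MW <= 0:
            raise ValueError(f"{self.id}: MW must be positive")
        for attr in ("nHdon", "nHacc"):
            v = getattr(self, attr)
            if int(v) != v or v < 0:
                raise ValueError(f"{self.id}: {attr} must be a non-negative integer")
        if self.RBN is not None and (int(self.RBN) != self.RBN or self.RBN < 0):
            raise ValueError(f"{self.id}: RBN must be a non-negative integer")
        if not 0.0 <= self.DL <= 1.0:
            raise ValueError(f"{self.id}: DL must lie in [0, 1]")
        if str(self.GI).strip().lower() not in {"high", "low"}:
            raise ValueError(f"{self.id}: GI class must be 'High' or 'Low'")


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs of the strict five-criterion ADME filter.

    Defaults are the conventional screening values: OB >= 30 %,
    Caco-2 strictly > -0.4 (components below are considered non-permeable),
    DL >= 0.18, GI class High, and a Lipinski pass tolerating at most one
    violation. OB and DL comparisons are inclusive; Caco-2 is strict.
    """

    min_ob: float = 30.0
    min_caco2: float = -0.4
    min_dl: float = 0.18
    gi_class: str = "High"
    max_lipinski_violations: int = 1


@dataclass
class ScreenReport:
    """Outcome of :func:`adme_screen`.

    ``table`` holds one row per component (indexed by id) with a boolean
    column per criterion plus ``strict_pass``, ``retained_via_whitelist`` and
    ``retained``. The invariant ``retained == strict_pass | retained_via_whitelist``
    holds by construction, and a whitelisted component is never also a strict
    pass.
    """

    table: pd.DataFrame
    thresholds: ScreenThresholds

    @property
    def strict_ids(self) -> frozenset:
        return frozenset(self.table.index[self.table["strict_pass"]])

    @property
    def retained_ids(self) -> frozenset:
        return frozenset(self.table.index[self.table["retained"]])

    def summary(self) -> dict:
        t = self.table
        return {
            "n_components": int(len(t)),
            "n_strict_pass": int(t["strict_pass"].sum()),
            "n_whitelist_addback": int(t["retained_via_whitelist"].sum()),
            "n_retained": int(t["retained"].sum()),
            "retained": sorted(self.retained_ids),
        }


def lipinski_check(rec: ComponentRecord, max_violations: int = 1) -> tuple[bool, int]:
    """Count rule-of-five violations and decide the pass flag.

    The conditions checked are MW <= 500, AlogP <= 5, H-bond donors <= 5,
    H-bond acceptors <= 10 and, when RBN is present, RBN <= 10. The
    conventional reading of the rule tolerates one violation, so the default
    ``max_violations`` is 1.
    """
    if max_violations < 0:
        raise ValueError("max_violations must be >= 0")
    conditions = [
        rec.MW <= 500,
        rec.AlogP <= 5,
        rec.nHdon <= 5,
        rec.nHacc <= 10,
    ]
    if rec.RBN is not None:
        conditions.append(rec.RBN <= 10)
    violations = sum(1 for ok in conditions if not ok)
    return violations <= max_violations, violations


def tanimoto_dl(a: Sequence[float], b: Sequence[float]) -> float:
    """Continuous Tanimoto similarity between two descriptor vectors.

    ``T(A, B) = (A . B) / (|A|^2 + |B|^2 - A . B)``

    With ``B`` set to the average descriptor vector of a reference drug
    library this is the drug-likeness index used to screen herbal
    components. The score is symmetric, equals 1 for identical non-zero
    vectors, and lies in [0, 1] for element-wise non-negative vectors.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.ndim != 1 or bv.ndim != 1:
        raise ValueError("descriptor vectors must be one-dimensional")
    if av.shape != bv.shape:
        raise ValueError(f"descriptor length mismatch: {av.size} vs {bv.size}")
    if not (np.isfinite(av).all() and np.isfinite(bv).all()):
        raise ValueError("descriptor vectors must be finite")
    dot = float(av @ bv)
    denom = float(av @ av) + float(bv @ bv) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined for two all-zero vectors")
    return dot / denom


def adme_screen(
    records: Iterable[ComponentRecord],
    thresholds: Optional[ScreenThresholds] = None,
    whitelist: Iterable[str] = (),
) -> ScreenReport:
    """Apply the strict five-criterion filter and the whitelist add-back.

    A component is a *strict pass* iff all five flags (OB, Caco-2, DL, GI,
    Lipinski) are true. The retained set is the union of strict passes and
    whitelisted components; ids on the whitelist that do not appear in the
    input trigger a warning, not an error.
    """
    thr = thresholds or ScreenThresholds()
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate component ids in input")
    wl = {str(w).strip() for w in whitelist if str(w).strip()}
    unknown = wl - set(ids)
    if unknown:
        warnings.warn(
            f"whitelist ids not present in the component table: {sorted(unknown)}",
            stacklevel=2,
        )

    rows = []
    for rec in records:
        lip_ok, lip_viol = lipinski_check(rec, thr.max_lipinski_violations)
        flags = {
            "ob_pass": rec.OB >= thr.min_ob,
            "caco2_pass": rec.Caco2 > thr.min_caco2,
            "dl_pass": rec.DL >= thr.min_dl,
            "gi_pass": rec.GI.strip().lower() == thr.gi_class.strip().lower(),
            "lipinski_pass": lip_ok,
        }
        strict = all(flags.values())
        via_wl = (rec.id in wl) and not strict
        failed = ",".join(k[:-5] for k, ok in flags.items() if not ok)
        rows.append(
            {
                "id": rec.id,
                "name": rec.name,
                **flags,
                "lipinski_violations": lip_viol,
                "strict_pass": strict,
                "retained_via_whitelist": via_wl,
                "retained": strict or via_wl,
                "failed_criteria": failed,
            }
        )
    table = pd.DataFrame(rows).set_index("id")
    return ScreenReport(table=table, thresholds=thr)


def read_components(path) -> list[ComponentRecord]:
    """Read a component property table (CSV).

    Expected header: ``id,name,MW,AlogP,nHdon,nHacc,TPSA,RBN,OB,Caco2,DL,GI``;
    an empty RBN cell marks the descriptor as unavailable.
    """
    df = pd.read_csv(path)
    required = {"id", "name", "MW", "AlogP", "nHdon", "nHacc", "TPSA", "OB", "Caco2", "DL", "GI"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"component table is missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        rbn = row.get("RBN")
        rbn = None if rbn is None or (isinstance(rbn, float) and math.isnan(rbn)) else int(rbn)
        records.append(
            ComponentRecord(
                id=str(row["id"]),
                name=str(row["name"]),
                MW=float(row["MW"]),
                AlogP=float(row["AlogP"]),
                nHdon=int(row["nHdon"]),
                nHacc=int(row["nHacc"]),
                TPSA=float(row["TPSA"]),
                OB=float(row["OB"]),
                Caco2=float(row["Caco2"]),
                DL=float(row["DL"]),
                GI=str(row["GI"]),
                RBN=rbn,
            )
        )
    return records
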