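"""Pedigree table serialization and study configuration files.

Pedigrees are stored as tab-separated tables, one row per member, with the
columns ``FamID, ID, sex, dadID, momID, affected, DA, birthYr, onsetYr,
deathYr, RR, available, proband`` (``DA`` is rare-variant carrier status).
Missing values are empty fields.  The dialect is a column-compatible
superset of the common pre-makeped pedigree layout (family, id, father,
mother, sex, affection).  Writing then reading a table reproduces the
pedigrees field-for-field.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml

from .ascertainment import AscertainedPair, StudyConfig
from .pedigree import Individual, Pedigree, PedigreeError

__all__ = [
    "PED_COLUMNS",
    "pedigrees_to_frame",
    "frame_to_pedigrees",
    "write_pedigree_table",
    "read_pedigrees",
    "write_pedigrees",
    "load_config",
]

PED_COLUMNS = [
    "FamID",
    "ID",
    "sex",
    "dadID",
    "momID",
    "affected",
    "DA",
    "birthYr",
    "onsetYr",
    "deathYr",
    "RR",
    "available",
    "proband",
]

_MISSING = ""


def _fmt_int(v: Optional[int]) -> str:
    return _MISSING if v is None else str(int(v))


def _fmt_bool(v: Optional[bool]) -> str:
    return _MISSING if v is None else ("1" if v else "0")


def _fmt_float(v: Optional[float]) -> str:
    return _MISSING if v is None else repr(float(v))


def pedigrees_to_frame(peds: Sequence[Pedigree]) -> pd.DataFrame:
    """All-string table of the given pedigrees, rows ordered by family,
    generation depth, then individual id."""
    rows: List[Dict[str, str]] = []
    for ped in peds:
        depth = ped.depth()
        ordered = sorted(ped.members, key=lambda i: (depth[i], i))
        for iid in ordered:
            m = ped[iid]
            rows.append(
                {
                    "FamID": str(ped.family_id),
                    "ID": str(m.individual_id),
                    "sex": m.sex,
                    "dadID": _fmt_int(m.father_id),
                    "momID": _fmt_int(m.mother_id),
                    "affected": _fmt_bool(m.affected),
                    "DA": _fmt_bool(m.carrier),
                    "birthYr": _fmt_int(m.birth_year),
                    "onsetYr": _fmt_int(m.onset_year),
                    "deathYr": _fmt_int(m.death_year),
                    "RR": _fmt_float(m.relative_risk),
                    "available": _fmt_bool(m.available),
                    "proband": _fmt_bool(m.proband),
                }
            )
    return pd.DataFrame(rows, columns=PED_COLUMNS, dtype=str)


def _parse_int(v: str) -> Optional[int]:
    return None if v == _MISSING else int(v)


def _parse_bool(v: str) -> Optional[bool]:
    return None if v == _MISSING else v == "1"


def _row_error(row: pd.Series, msg: str) -> PedigreeError:
    return PedigreeError(f"FamID {row['FamID']}, ID {row['ID']}: {msg}")


def frame_to_pedigrees(df: pd.DataFrame) -> List[Pedigree]:
    """Rebuild validated pedigrees from a table in the dialect above.

    Rejects duplicate (FamID, ID) pairs, dangling parent references and
    cyclic parentage, naming the offending row.
    """
    missing_cols = [c for c in PED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PedigreeError(f"pedigree table missing column(s): {', '.join(missing_cols)}")
    peds: List[Pedigree] = []
    for fam_id, fam in df.groupby("FamID", sort=True):
        ped = Pedigree(int(fam_id))
        for _, row in fam.iterrows():
            iid = int(row["ID"])
            if iid in ped:
                raise _row_error(row, "duplicate individual id")
            affected = _parse_bool(row["affected"])
            rr = row["RR"]
            ind = Individual(
                family_id=int(fam_id),
                individual_id=iid,
                sex=row["sex"],
                father_id=_parse_int(row["dadID"]),
                mother_id=_parse_int(row["momID"]),
                carrier=bool(_parse_bool(row["DA"])),
                affected=affected,
                birth_year=_parse_int(row["birthYr"]),
                onset_year=_parse_int(row["onsetYr"]),
                death_year=_parse_int(row["deathYr"]),
                available=bool(_parse_bool(row["available"])),
                proband=bool(_parse_bool(row["proband"])),
                relative_risk=None if rr == _MISSING else float(rr),
            )
            ped.add(ind)
        try:
            ped.validate()
        except PedigreeError as exc:
            raise PedigreeError(f"FamID {fam_id}: {exc}") from None
        peds.append(ped)
    return peds


def write_pedigree_table(peds: Sequence[Pedigree], path) -> None:
    pedigrees_to_frame(peds).to_csv(path, sep="\t", index=False)


def read_pedigrees(path) -> List[Pedigree]:
    """Read pedigrees from a tab-separated table; empty file gives ``[]``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pedigree table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return []
    return frame_to_pedigrees(df)


def write_pedigrees(study: Sequence[AscertainedPair], out_dir) -> Dict[str, Path]:
    """Write one table of full pedigrees and one of ascertained pedigrees.

    Returns the two paths under keys ``full`` and ``ascertained``.
    """
    if not study:
        raise ValueError("study is empty; nothing to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "full": out / "full_peds.tsv",
        "ascertained": out / "ascertained_peds.tsv",
    }
    write_pedigree_table([p.full_ped for p in study], paths["full"])
    write_pedigree_table([p.ascertained_ped for p in study], paths["ascertained"])
    return paths


_TUPLE_FIELDS = ("ascertain_span", "founder_birth_range")


def load_config(path, **overrides) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML; keyword overrides win.

    Keys mirror the StudyConfig field names one-to-one; ``recall_probs``
    may be the string ``"default"`` or a list of probabilities.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(raw) - set(StudyConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"config file {path}: unknown key(s) {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    for key in _TUPLE_FIELDS:
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if isinstance(raw.get("recall_probs"), list):
        raw["recall_probs"] = tuple(raw["recall_probs"])
    return StudyConfig(**raw)
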