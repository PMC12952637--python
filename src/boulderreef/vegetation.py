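"""Rule-based classification of macroalgal vegetation on boulders.

Each boulder carries presence/absence of five scored taxa: *Undaria
pinnatifida*, perennial *Sargassum* spp., *Sargassum horneri*, *Colpomenia
sinuosa* and geniculate coralline red algae. A priority cascade maps the
32 possible presence patterns to seven community types with ordinal scores
0-6, ranked by persistence, canopy height and structural value of the bed:

====== =============================== ==========================================
score  community                       rule (first match wins)
====== =============================== ==========================================
6      Sargassum & U. pinnatifida      perennial Sargassum AND U. pinnatifida
5      Sargassum                       perennial Sargassum
4      S. horneri                      S. horneri
3      U. pinnatifida                  U. pinnatifida
2      coralline red algae             coralline
1      C. sinuosa                      C. sinuosa
0      bare rock                       nothing present
====== =============================== ==========================================

Scores >= 3 count as "rich" vegetation (persistent canopy-forming beds),
<= 2 as "poor" (ephemeral or crustose cover only).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .geomorph import BOTTOM_TYPES, GeomorphicIndicators

SPECIES = ("u_pinnatifida", "perennial_sargassum", "s_horneri", "c_sinuosa", "coralline")

#: S8-schema CSV column names, in canonical order.
S8_COLUMNS = (
    "U. pinnatifida",
    "Perennial Sargassum spp.",
    "S. horneri",
    "C. sinuosa",
    "Geniculate coralline red algae",
    "Bottom type",
    "Vegetation type",
    "Relative Height",
    "Surface Complexity",
)

_S8_SPECIES_COLS = dict(zip(SPECIES, S8_COLUMNS[:5]))

COMMUNITIES = (
    "bare_rock",
    "c_sinuosa",
    "coralline",
    "u_pinnatifida",
    "s_horneri",
    "sargassum",
    "sargassum_u_pinnatifida",
)

#: community label <-> score bijection (index in COMMUNITIES == score)
COMMUNITY_SCORE = {name: score for score, name in enumerate(COMMUNITIES)}

COMMUNITY_DISPLAY = {
    "sargassum_u_pinnatifida": "Sargassum & U. pinnatifida community",
    "sargassum": "Sargassum community",
    "s_horneri": "S. horneri community",
    "u_pinnatifida": "U. pinnatifida community",
    "coralline": "Coralline red algae community",
    "c_sinuosa": "C. sinuosa community",
    "bare_rock": "Bare rock",
}
_DISPLAY_TO_COMMUNITY = {v: k for k, v in COMMUNITY_DISPLAY.items()}


@dataclass(frozen=True)
class SpeciesPresence:
    u_pinnatifida: bool
    perennial_sargassum: bool
    s_horneri: bool
    c_sinuosa: bool
    coralline: bool

    def as_tuple(self) -> tuple[bool, ...]:
        return tuple(getattr(self, s) for s in SPECIES)

    @classmethod
    def all_combinations(cls) -> list["SpeciesPresence"]:
        return [cls(*bits) for bits in product([True, False], repeat=5)]


@dataclass
class VegetationRecord:
    boulder_id: str
    presence: SpeciesPresence
    bottom_type: str
    community: str | None = None
    score: int | None = None
    indicators: GeomorphicIndicators | None = None

    def classify(self) -> "VegetationRecord":
        self.community, self.score = classify_vegetation(self.presence)
        return self


def classify_vegetation(presence: SpeciesPresence) -> tuple[str, int]:
    """Map a five-species presence pattern to (community, score).

    Total and deterministic over all 32 combinations; wildcard rows of the
    scoresheet are realised as a priority cascade (a perennial-Sargassum
    bed with an understorey still scores as the Sargassum community, etc.).
    """
    p = presence
    if p.perennial_sargassum and p.u_pinnatifida:
        name = "sargassum_u_pinnatifida"
    elif p.perennial_sargassum:
        name = "sargassum"
    elif p.s_horneri:
        name = "s_horneri"
    elif p.u_pinnatifida:
        name = "u_pinnatifida"
    elif p.coralline:
        name = "coralline"
    elif p.c_sinuosa:
        name = "c_sinuosa"
    else:
        name = "bare_rock"
    return name, COMMUNITY_SCORE[name]


def richness_dichotomy(score: int) -> str:
    """Binarise a 0-6 vegetation score: 'rich' for >= 3, 'poor' for <= 2."""
    score = int(score)
    if not 0 <= score <= 6:
        raise ValueError(f"vegetation score must be in 0..6, got {score}")
    return "rich" if score >= 3 else "poor"


_TRUE_TOKENS = {"+"}
_FALSE_TOKENS = {"-", "−", "–", ""}  # ASCII hyphen, minus sign, en dash, blank


def _parse_presence_token(tok, column: str) -> bool:
    s = str(tok).strip() if not pd.isna(tok) else ""
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValueError(f"column {column!r}: unknown presence token {tok!r} (expected '+' or '-')")


def _parse_bottom_type(tok) -> str:
    s = str(tok).strip().lower()
    if s.startswith("sand"):
        return "sand"
    if s.startswith("cobble") or "cobble" in s:
        return "cobble"
    raise ValueError(f"unknown bottom type {tok!r} (expected sand or cobble)")


def read_s8_table(path) -> list[VegetationRecord]:
    """Read a presence table in the S8 schema (five species columns with
    '+'/'-' tokens, bottom type, optional stored vegetation type and
    indicator columns). Unicode minus and ASCII hyphen both mean absent.
    Row count is preserved; every row becomes a classified record."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in S8_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"S8 table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        presence = SpeciesPresence(
            **{
                sp: _parse_presence_token(row[col], col)
                for sp, col in _S8_SPECIES_COLS.items()
            }
        )
        indicators = None
        if "Relative Height" in df.columns and "Surface Complexity" in df.columns:
            rh, sc = row.get("Relative Height"), row.get("Surface Complexity")
            if not (pd.isna(rh) or pd.isna(sc)):
                indicators = GeomorphicIndicators(
                    relative_height=float(rh),
                    surface_complexity=float(sc),
                    valid=True,
                )
        rec = VegetationRecord(
            boulder_id=str(row.get("boulder_id", i)),
            presence=presence,
            bottom_type=_parse_bottom_type(row["Bottom type"]),
            indicators=indicators,
        ).classify()
        records.append(rec)
    return records


def write_s8_table(records: list[VegetationRecord], path) -> None:
    """Write classified records as S8-schema CSV (ASCII '-' for absence)."""
    rows = []
    for r in records:
        if r.community is None:
            r = VegetationRecord(**{**r.__dict__}).classify()
        row = {
            col: "+" if flag else "-"
            for col, flag in zip(S8_COLUMNS[:5], r.presence.as_tuple())
        }
        row["Bottom type"] = r.bottom_type
        row["Vegetation type"] = COMMUNITY_DISPLAY[r.community]
        row["Relative Height"] = (
            "" if r.indicators is None or r.indicators.relative_height is None
            else r.indicators.relative_height
        )
        row["Surface Complexity"] = (
            "" if r.indicators is None or r.indicators.surface_complexity is None
            else r.indicators.surface_complexity
        )
        row["boulder_id"] = r.boulder_id
        rows.append(row)
    pd.DataFrame(rows, columns=["boulder_id", *S8_COLUMNS]).to_csv(path, index=False)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 at 1 digit -> 0.1), matching the
    conventional printed style rather than banker's rounding."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 1) if total else float("nan")


def tabulate_prevalence(records: list[VegetationRecord]) -> pd.DataFrame:
    """Per-species presence counts and percentages, overall and stratified
    by bottom type. Index: species; columns: count/pct x overall/sand/cobble."""
    if not records:
        raise ValueError("no records")
    strata = {"overall": records}
    for bt in BOTTOM_TYPES:
        strata[bt] = [r for r in records if r.bottom_type == bt]
    out = {}
    for name, recs in strata.items():
        n = len(recs)
        out[f"n_{name}"] = {sp: n for sp in SPECIES}
        out[f"count_{name}"] = {
            sp: sum(getattr(r.presence, sp) for r in recs) for sp in SPECIES
        }
        out[f"pct_{name}"] = {
            sp: _pct(out[f"count_{name}"][sp], n) for sp in SPECIES
        }
    return pd.DataFrame(out).loc[list(SPECIES)]


def tabulate_communities(records: list[VegetationRecord]) -> dict[str, pd.DataFrame]:
    """Community counts/percentages overall and per bottom type, plus the
    per-combination breakdown (one row per distinct 5-flag pattern with
    sand/cobble/total counts, grouped by community).

    Returns {'communities': ..., 'combinations': ...}."""
    if not records:
        raise ValueError("no records")
    recs = [r if r.community is not None else r.classify() for r in records]

    comm = {}
    strata = {"overall": recs}
    for bt in BOTTOM_TYPES:
        strata[bt] = [r for r in recs if r.bottom_type == bt]
    for name, rs in strata.items():
        n = len(rs)
        counts = {c: sum(r.community == c for r in rs) for c in COMMUNITIES}
        comm[f"count_{name}"] = counts
        comm[f"pct_{name}"] = {c: _pct(counts[c], n) for c in COMMUNITIES}
    communities = pd.DataFrame(comm).loc[list(COMMUNITIES)]

    combo_rows = []
    for presence in SpeciesPresence.all_combinations():
        matching = [r for r in recs if r.presence == presence]
        if not matching:
            continue
        community, score = classify_vegetation(presence)
        pattern = "".join("+" if f else "-" for f in presence.as_tuple())
        combo_rows.append(
            {
                "pattern": pattern,
                "community": community,
                "score": score,
                "sand": sum(r.bottom_type == "sand" for r in matching),
                "cobble": sum(r.bottom_type == "cobble" for r in matching),
                "total": len(matching),
            }
        )
    combinations = (
        pd.DataFrame(combo_rows)
        .sort_values(["score", "pattern"], ascending=[False, False])
        .reset_index(drop=True)
    )
    return {"communities": communities, "combinations": combinations}
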