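"""ICD-10 taxonomy handling.

Collapses raw three-digit (or longer) ICD-10 diagnosis codes into combined
disease categories, keeps only the first occurrence per participant and
category, applies chapter-level exclusions, and groups cause-of-death codes
into a fixed 16-category chapter scheme.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import MappingError

logger = logging.getLogger(__name__)

_ICD3 = re.compile(r"^[A-Z][0-9]{2}$")

#: Chapters dropped from the analysis by default: pregnancy/childbirth (O)
#: and symptoms/signs not elsewhere classified (R).
DEFAULT_EXCLUDED_CHAPTERS = frozenset({"O", "R"})


@dataclass(frozen=True)
class CodeMapping:
    """Validated ICD-10 -> combined-category mapping.

    ``entries`` maps a 3-character ICD-10 code to ``(combined_code,
    description)``. Each source code belongs to exactly one combined
    category.
    """

    entries: Mapping[str, tuple[str, str]]
    excluded_chapters: frozenset = DEFAULT_EXCLUDED_CHAPTERS

    @property
    def categories(self) -> set[str]:
        return {cat for cat, _ in self.entries.values()}

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def category_of(self, code: str) -> str | None:
        entry = self.entries.get(code)
        return entry[0] if entry is not None else None

    def description_of(self, category: str) -> str:
        for cat, desc in self.entries.values():
            if cat == category:
                return desc
        return ""


def truncate_code(code: str) -> str:
    """Normalize an ICD-10 code to its 3-character form (e.g. K760 -> K76)."""
    return str(code).strip().upper()[:3]


def load_mapping(path, excluded_chapters: Iterable[str] | None = None) -> CodeMapping:
    """Load a tab-separated ``icd10_code, combined_code[, description]`` file.

    Duplicate rows with the same category are deduplicated silently; a code
    listed with two different categories is a hard error, as is any malformed
    code (reported with its line number).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"icd10_code", "combined_code"}
    if not required.issubset(df.columns):
        raise MappingError(
            f"mapping file {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if "description" not in df.columns:
        df["description"] = ""
    entries: dict[str, tuple[str, str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        code = str(row.icd10_code).strip().upper()
        if not _ICD3.fullmatch(code):
            raise MappingError(f"{path}: line {i}: malformed ICD-10 code {code!r}")
        entry = (str(row.combined_code).strip(), str(row.description).strip())
        if code in entries:
            if entries[code][0] != entry[0]:
                raise MappingError(
                    f"{path}: line {i}: code {code} mapped to both "
                    f"{entries[code][0]!r} and {entry[0]!r}"
                )
            continue
        entries[code] = entry
    mapping = CodeMapping(
        entries=entries,
        excluded_chapters=(
            frozenset(excluded_chapters)
            if excluded_chapters is not None
            else DEFAULT_EXCLUDED_CHAPTERS
        ),
    )
    logger.info("loaded %d codes -> %d categories", len(entries), mapping.n_categories)
    return mapping


def default_mapping(excluded_chapters: Iterable[str] | None = None) -> CodeMapping:
    """Small built-in mapping shipped with the package (testing default)."""
    with resources.as_file(
        resources.files("mafld_traj.data") / "default_mapping.tsv"
    ) as p:
        return load_mapping(p, excluded_chapters=excluded_chapters)


def identity_mapping(
    codes: Iterable[str],
    descriptions: Mapping[str, str] | None = None,
    excluded_chapters: Iterable[str] = (),
) -> CodeMapping:
    """Mapping where each code is its own category (synthetic catalogs)."""
    descriptions = descriptions or {}
    entries = {}
    for code in codes:
        code = truncate_code(code)
        if not _ICD3.fullmatch(code):
            raise MappingError(f"identity mapping: malformed code {code!r}")
        entries[code] = (code, descriptions.get(code, code))
    return CodeMapping(entries=entries, excluded_chapters=frozenset(excluded_chapters))


def collapse_events(
    raw: pd.DataFrame,
    mapping: CodeMapping,
    unmapped: str = "drop",
) -> pd.DataFrame:
    """Collapse raw diagnoses into deduplicated first-occurrence events.

    Parameters
    ----------
    raw
        Columns ``participant_id``, ``icd10_code`` (or ``category`` for
        already-collapsed input, making the operation idempotent), ``date``.
    mapping
        The code mapping; codes already equal to a combined category pass
        through unchanged.
    unmapped
        ``"drop"`` skips codes absent from the mapping with a warning;
        ``"strict"`` raises.

    Returns a frame with columns ``participant_id, category, date`` sorted by
    (participant_id, category); at most one row per pair, earliest date kept.
    """
    if unmapped not in {"drop", "strict"}:
        raise ValueError(f"unknown unmapped policy {unmapped!r}")
    out_cols = ["participant_id", "category", "date"]
    if raw.empty:
        return pd.DataFrame(columns=out_cols)
    raw = raw.copy()
    code_col = "icd10_code" if "icd10_code" in raw.columns else "category"
    try:
        raw["date"] = pd.to_datetime(raw["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise MappingError(f"unparseable diagnosis date: {exc}") from exc

    combined = {cat for cat, _ in mapping.entries.values()}
    codes = raw[code_col].astype(str).str.strip().str.upper()
    is_combined = codes.isin(combined)
    truncated = codes.where(is_combined, codes.str[:3])

    chapters = truncated.str[:1]
    keep = ~chapters.isin(mapping.excluded_chapters)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d records from chapters %s", n_excluded,
                    sorted(mapping.excluded_chapters))

    category = truncated.where(
        is_combined, truncated.map(lambda c: mapping.category_of(c))
    )
    unmapped_mask = category.isna() & keep
    if unmapped_mask.any():
        bad = sorted(truncated[unmapped_mask].unique())
        if unmapped == "strict":
            raise MappingError(f"unmapped ICD-10 codes: {bad}")
        logger.warning("dropping %d records with unmapped codes %s",
                       int(unmapped_mask.sum()), bad)
    keep &= category.notna()

    events = pd.DataFrame(
        {
            "participant_id": raw["participant_id"],
            "category": category,
            "date": raw["date"],
        }
    )[keep.to_numpy()]
    events = (
        events.groupby(["participant_id", "category"], as_index=False, sort=True)["date"]
        .min()
    )
    return events[out_cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cause-of-death grouping (16 chapter-level categories)

def load_death_scheme(path=None) -> dict[str, tuple[str, str]]:
    """Load chapter -> (cause_code, description); default ships 16 causes."""
    if path is None:
        ctx = resources.as_file(resources.files("mafld_traj.data") / "death_causes.tsv")
        with ctx as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chapter", "cause_code"}
    if not required.issubset(df.columns):
        raise MappingError(f"death scheme must have columns {sorted(required)}")
    if "description" not in df.columns:
        df["description"] = df["cause_code"]
    return {
        str(r.chapter).strip().upper(): (str(r.cause_code).strip(), str(r.description))
        for r in df.itertuples(index=False)
    }


def n_death_causes(scheme: Mapping[str, tuple[str, str]]) -> int:
    return len({cause for cause, _ in scheme.values()})


def group_death_causes(
    codes: Iterable[str], scheme: Mapping[str, tuple[str, str]]
) -> set[str]:
    """Map primary/secondary ICD-10 death codes to cause categories."""
    causes: set[str] = set()
    for code in codes:
        code = truncate_code(code)
        if not code:
            continue
        entry = scheme.get(code[0])
        if entry is None:
            logger.warning("death code %s outside the cause scheme; dropped", code)
            continue
        causes.add(entry[0])
    return causes


def chapter_group(category: str, scheme: Mapping[str, tuple[str, str]]) -> str | None:
    """Chapter-level group of a disease category (for sensitivity exclusion)."""
    entry = scheme.get(truncate_code(category)[:1])
    return entry[0] if entry is not None else None


def prepare_deaths(
    deaths_raw: pd.DataFrame, scheme: Mapping[str, tuple[str, str]]
) -> pd.DataFrame:
    """Parse a raw death table into (participant_id, date, causes frozenset).

    ``cause_codes`` is a semicolon-joined list of ICD-10 codes (primary first).
    """
    cols = ["participant_id", "date", "causes"]
    if deaths_raw.empty:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(
        {
            "participant_id": deaths_raw["participant_id"],
            "date": pd.to_datetime(deaths_raw["date"], format="ISO8601"),
            "causes": deaths_raw["cause_codes"]
            .astype(str)
            .map(lambda s: frozenset(group_death_causes(s.split(";"), scheme))),
        }
    )
    return out[cols].reset_index(drop=True)
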