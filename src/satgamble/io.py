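"""Readers and writers for the respondent and distribution CSV formats.

Respondent files are long-format UTF-8 CSV with a ``record`` discriminator:
one ``participant`` row per respondent carrying the scalar fields, and one
``ladder`` row per (participant, gamble, ladder step). Probabilities are
stored as the exact grid strings ("1/2" … "1/1000000"). The writer/reader
pair is a lossless round trip on valid data; malformed rows are rejected
with their file row number, never silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import (
    DEFAULT_BIN_REPRESENTATIVES,
    LIVING_STATES,
    LS_BIN_LABELS,
    PROBABILITY_GRID_LABELS,
    BinnedLSDistribution,
    Block,
    Context,
    Decision,
    FormatError,
    GambleSpec,
    LadderResponse,
    Respondent,
    SchemaError,
    State,
    ValidationError,
)

PARTICIPANT_COLUMNS = [
    "record",
    "participant_id",
    "condition",
    "age_band",
    "sex",
    "party",
    "pol_1",
    "pol_2",
    "pol_3",
    "pol_4",
    "pol_5",
    "rating_A",
    "rating_B",
    "rating_C",
    "rating_D",
    "rating_E",
    "attention_fail",
]

LADDER_COLUMNS = [
    "record",
    "participant_id",
    "gamble_index",
    "context",
    "block",
    "baseline",
    "win",
    "lose",
    "step_index",
    "probability",
    "decision",
]

ALL_COLUMNS = PARTICIPANT_COLUMNS + [
    c for c in LADDER_COLUMNS if c not in PARTICIPANT_COLUMNS
]


def write_respondents(respondents: Sequence[Respondent], path: str | Path) -> None:
    """Write respondents to a long-format CSV (see module docstring)."""
    rows: list[dict] = []
    for r in respondents:
        row = {c: "" for c in ALL_COLUMNS}
        row.update(
            record="participant",
            participant_id=r.id,
            condition=r.condition,
            age_band=r.age_band,
            sex=r.sex,
            party=r.party,
            attention_fail=int(r.attention_fail),
        )
        for i, item in enumerate(r.political_items, start=1):
            row[f"pol_{i}"] = int(item)
        for s in LIVING_STATES:
            row[f"rating_{s.name}"] = int(r.vignette_ratings[s])
        rows.append(row)
        for g_idx, lad in enumerate(r.ladders):
            for s_idx, (prob, dec) in enumerate(lad.decisions):
                lrow = {c: "" for c in ALL_COLUMNS}
                lrow.update(
                    record="ladder",
                    participant_id=r.id,
                    gamble_index=g_idx,
                    context=lad.gamble.context.value,
                    block=lad.gamble.block.value,
                    baseline=lad.gamble.baseline.name,
                    win=lad.gamble.win.name,
                    lose=lad.gamble.lose.name,
                    step_index=s_idx,
                    probability=prob,
                    decision=dec.value,
                )
                rows.append(lrow)
    df = pd.DataFrame(rows, columns=ALL_COLUMNS)
    df.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, path: Path) -> None:
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_respondents(path: str | Path) -> list[Respondent]:
    """Read a long-format respondent CSV; raises ``SchemaError`` /
    ``FormatError`` / ``ValidationError`` with file row numbers on bad input."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, path)

    participants: dict[str, dict] = {}
    ladder_rows: dict[str, list[tuple[int, pd.Series]]] = {}
    for idx, row in df.iterrows():
        file_row = int(idx) + 2  # header is row 1
        kind = row["record"]
        pid = row["participant_id"]
        if kind == "participant":
            if pid in participants:
                raise FormatError(
                    f"{path} row {file_row}: duplicate participant {pid!r}"
                )
            participants[pid] = {"row": file_row, "data": row}
        elif kind == "ladder":
            ladder_rows.setdefault(pid, []).append((file_row, row))
        else:
            raise FormatError(
                f"{path} row {file_row}: unknown record type {kind!r}"
            )

    respondents: list[Respondent] = []
    for pid, info in participants.items():
        row = info["data"]
        file_row = info["row"]
        try:
            items = tuple(int(row[f"pol_{i}"]) for i in range(1, 6))
            ratings = {
                s: int(row[f"rating_{s.name}"]) for s in LIVING_STATES
            }
            attention_fail = bool(int(row["attention_fail"]))
        except ValueError as exc:
            raise FormatError(f"{path} row {file_row}: {exc}") from exc

        ladders = _assemble_ladders(ladder_rows.get(pid, []), path)
        try:
            respondents.append(
                Respondent(
                    id=pid,
                    condition=row["condition"],
                    age_band=row["age_band"],
                    sex=row["sex"],
                    party=row["party"],
                    political_items=items,
                    vignette_ratings=ratings,
                    ladders=ladders,
                    attention_fail=attention_fail,
                )
            )
        except ValidationError as exc:
            raise ValidationError(
                f"{path} row {file_row} (participant {pid!r}): {exc}"
            ) from exc
    orphans = set(ladder_rows) - set(participants)
    if orphans:
        raise FormatError(
            f"{path}: ladder rows for unknown participants {sorted(orphans)}"
        )
    return respondents


def _assemble_ladders(
    rows: list[tuple[int, pd.Series]], path: Path
) -> tuple[LadderResponse, ...]:
    by_gamble: dict[int, list[tuple[int, pd.Series]]] = {}
    for file_row, row in rows:
        try:
            g_idx = int(row["gamble_index"])
        except ValueError as exc:
            raise FormatError(f"{path} row {file_row}: {exc}") from exc
        by_gamble.setdefault(g_idx, []).append((file_row, row))

    ladders = []
    for g_idx in sorted(by_gamble):
        steps = sorted(by_gamble[g_idx], key=lambda fr: int(fr[1]["step_index"]))
        first_row, first = steps[0]
        try:
            gamble = GambleSpec(
                baseline=State[first["baseline"]],
                win=State[first["win"]],
                lose=State[first["lose"]],
                context=Context(first["context"]),
                block=Block(first["block"]),
            )
        except (KeyError, ValueError, ValidationError) as exc:
            raise FormatError(f"{path} row {first_row}: {exc}") from exc
        decisions = []
        for file_row, row in steps:
            prob = row["probability"]
            if prob not in PROBABILITY_GRID_LABELS:
                raise FormatError(
                    f"{path} row {file_row}: probability {prob!r} is not on "
                    "the ladder grid"
                )
            try:
                decisions.append((prob, Decision(row["decision"])))
            except ValueError as exc:
                raise FormatError(f"{path} row {file_row}: {exc}") from exc
        try:
            ladders.append(LadderResponse(gamble=gamble, decisions=tuple(decisions)))
        except ValidationError as exc:
            raise ValidationError(
                f"{path} row {first_row} (gamble {g_idx}): {exc}"
            ) from exc
    return tuple(ladders)


def write_distribution(dist: BinnedLSDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {
            "ls_range": LS_BIN_LABELS,
            "share": dist.shares,
            "representative_ls": dist.representatives,
        }
    ).to_csv(path, index=False)


def read_distribution(
    path: str | Path, normalize: bool = False
) -> BinnedLSDistribution:
    """Read a binned life-satisfaction distribution CSV with columns
    ``ls_range``, ``share`` and optional ``representative_ls``.

    Shares must sum to 1 within 1e-9 unless ``normalize`` is set, in which
    case they are rescaled.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("ls_range", "share"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if list(df["ls_range"]) != list(LS_BIN_LABELS):
        raise SchemaError(
            f"{path}: ls_range must be exactly {list(LS_BIN_LABELS)}, got "
            f"{list(df['ls_range'])}"
        )
    shares = [float(s) for s in df["share"]]
    if any(s < 0 for s in shares):
        raise FormatError(f"{path}: negative share")
    total = sum(shares)
    if normalize:
        if total <= 0:
            raise FormatError(f"{path}: shares sum to {total}")
        shares = [s / total for s in shares]
    elif abs(total - 1.0) > 1e-9:
        raise FormatError(
            f"{path}: shares sum to {total!r}; pass normalize=True to rescale"
        )
    if "representative_ls" in df.columns:
        reps = tuple(float(r) for r in df["representative_ls"])
    else:
        reps = DEFAULT_BIN_REPRESENTATIVES
    return BinnedLSDistribution(shares=tuple(shares), representatives=reps)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
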