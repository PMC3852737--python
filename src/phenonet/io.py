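"""Reading observation/species/phenophase tables and writing network exports.

Input files are plain CSV or TSV.  Column names (or 0-based positions) are
supplied through :class:`ColumnMap` rather than fixed headers, since field
datasets rarely agree on a header convention.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, ParseError
from .types import (
    GUILDS,
    PLANT,
    POLLINATOR,
    BipartiteNetwork,
    ObservationRecord,
    Phenophase,
    SpeciesInfo,
)

PathOrBuffer = Union[str, Path, TextIO]


@dataclass(frozen=True)
class ColumnMap:
    """Maps logical observation fields to file columns (names or positions)."""

    day: Union[str, int] = "day"
    plant: Union[str, int] = "plant_id"
    pollinator: Union[str, int] = "pollinator_id"
    count: Optional[Union[str, int]] = None
    sep: Optional[str] = None  # None: sniff ',' vs tab from the first line
    header: bool = True


def _read_table(source: PathOrBuffer, cmap: ColumnMap) -> pd.DataFrame:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    if not text.strip():
        raise ParseError("input table is empty")
    sep = cmap.sep
    if sep is None:
        first = text.splitlines()[0]
        sep = "\t" if "\t" in first else ","
    return pd.read_csv(
        _io.StringIO(text),
        sep=sep,
        header=0 if cmap.header else None,
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=True,
    )


def _column(df: pd.DataFrame, key: Union[str, int], what: str) -> pd.Series:
    if isinstance(key, int):
        if key >= df.shape[1]:
            raise ConfigurationError(
                f"{what} column index {key} out of range ({df.shape[1]} columns)"
            )
        return df.iloc[:, key]
    if key not in df.columns:
        raise ConfigurationError(
            f"missing {what} column {key!r}; file has columns {list(df.columns)}"
        )
    return df[key]


def read_observations(
    source: PathOrBuffer, columns: ColumnMap = ColumnMap()
) -> list[ObservationRecord]:
    """Parse observation records, preserving row order.

    Raises :class:`ConfigurationError` when a mapped column is absent and
    :class:`ParseError` (naming the file line) when a day or count does not
    parse as an integer.  Extra columns are ignored.
    """
    df = _read_table(source, columns)
    days = _column(df, columns.day, "day")
    plants = _column(df, columns.plant, "plant")
    polls = _column(df, columns.pollinator, "pollinator")
    counts = _column(df, columns.count, "count") if columns.count is not None else None
    header_offset = 2 if columns.header else 1  # 1-based file line of first data row
    records = []
    for i in range(len(df)):
        line = i + header_offset
        try:
            day = int(str(days.iloc[i]).strip())
        except ValueError:
            raise ParseError(
                f"line {line}: day value {days.iloc[i]!r} is not an integer"
            ) from None
        count = 1
        if counts is not None:
            raw = str(counts.iloc[i]).strip()
            if raw:
                try:
                    count = int(raw)
                except ValueError:
                    raise ParseError(
                        f"line {line}: count value {raw!r} is not an integer"
                    ) from None
        records.append(
            ObservationRecord(day, str(plants.iloc[i]).strip(), str(polls.iloc[i]).strip(), count)
        )
    return records


def read_species(source: PathOrBuffer) -> dict[str, SpeciesInfo]:
    """Read a species table with columns id, guild[, group, trophic_role]."""
    df = _read_table(source, ColumnMap())
    for col in ("id", "guild"):
        if col not in df.columns:
            raise ConfigurationError(f"species table missing column {col!r}")
    out: dict[str, SpeciesInfo] = {}
    for i, row in df.iterrows():
        sid = row["id"].strip()
        if sid in out:
            raise ParseError(f"duplicate species id {sid!r}")
        guild = row["guild"].strip()
        if guild not in GUILDS:
            raise ParseError(f"species {sid!r}: guild must be one of {GUILDS}, got {guild!r}")
        group = row["group"].strip() if "group" in df.columns and row["group"].strip() else None
        role = (
            row["trophic_role"].strip()
            if "trophic_role" in df.columns and row["trophic_role"].strip()
            else None
        )
        out[sid] = SpeciesInfo(sid, guild, group, role)
    return out


def read_phenophases(source: PathOrBuffer) -> dict[str, Phenophase]:
    """Read an explicit phenophase table (id, start_day, end_day)."""
    df = _read_table(source, ColumnMap())
    for col in ("id", "start_day", "end_day"):
        if col not in df.columns:
            raise ConfigurationError(f"phenophase table missing column {col!r}")
    out: dict[str, Phenophase] = {}
    for i, row in df.iterrows():
        sid = row["id"].strip()
        try:
            start, end = int(row["start_day"]), int(row["end_day"])
        except ValueError:
            raise ParseError(f"line {i + 2}: non-integer phenophase bounds") from None
        out[sid] = Phenophase(sid, start, end)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_edgelist(nets: Union[BipartiteNetwork, Sequence[BipartiteNetwork]],
                   path: Union[str, Path]) -> None:
    """Write one or several networks as a flat edge-list CSV.

    Columns: plant_id, pollinator_id, window_start, window_end — the
    time-ordered export of a windowed series (one row per link per window).
    """
    if isinstance(nets, BipartiteNetwork):
        nets = [nets]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plant_id", "pollinator_id", "window_start", "window_end"])
        for net in nets:
            ws, we = net.window if net.window else ("", "")
            for p, a in sorted(net.links):
                w.writerow([p, a, ws, we])


def to_graph(net: BipartiteNetwork) -> nx.Graph:
    """The network as an undirected networkx graph with a bipartite attribute."""
    g = nx.Graph()
    g.add_nodes_from(sorted(net.plants), guild=PLANT, bipartite=0)
    g.add_nodes_from(sorted(net.pollinators), guild=POLLINATOR, bipartite=1)
    g.add_edges_from(sorted(net.links))
    return g


def write_graphml(net: BipartiteNetwork, path: Union[str, Path]) -> None:
    nx.write_graphml(to_graph(net), path)


def summary_to_json(summary, path: Union[str, Path]) -> None:
    """Write a NetworkSummary (or any to_dict-able object) as JSON."""
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
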