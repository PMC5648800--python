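"""File formats and configuration.

FASTA carries sequence libraries with a ``>name|role`` header
micro-dialect (roles: target, star, split_A, split_B; a bare header
defaults to target), so one file can hold paired STAR/target libraries.
Crosstalk matrices are TSV with a ``star\\target`` corner cell.  Design
configuration and scaffold definitions are flat YAML.  All writers are
deterministic: stable ordering and fixed numeric formatting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .crosstalk import CrosstalkMatrix
from .design import DesignConfig, StarDesign, TerminatorScaffold
from .errors import AlphabetError, ConfigError, FormatError, ScaffoldError
from .sequences import normalize

__all__ = [
    "LibraryRecord",
    "ROLES",
    "read_fasta",
    "write_fasta",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "load_config",
    "load_scaffold",
    "write_scaffold",
    "write_library",
    "read_library",
]

ROLES = ("target", "star", "split_A", "split_B")

_FASTA_WRAP = 60


@dataclass(frozen=True)
class LibraryRecord:
    """One sequence record: (name, role) is unique within a file."""

    name: str
    role: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(f"unknown role {self.role!r} (expected one of {ROLES})")
        object.__setattr__(self, "sequence", normalize(self.sequence))


def read_fasta(path: Union[str, Path]) -> List[LibraryRecord]:
    """Parse a ``>name|role`` FASTA file into library records.

    Bare headers default to role=target; T is normalized to U and case is
    folded; line wrapping is ignored.  Duplicate (name, role) headers and
    non-ACGU symbols are format errors (the latter reported with the
    offending line number).
    """
    path = Path(path)
    records: List[LibraryRecord] = []
    seen: set[tuple[str, str]] = set()
    header: Optional[tuple[str, str]] = None
    chunks: List[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        name, role = header
        try:
            seq = normalize("".join(chunks))
        except AlphabetError as exc:
            raise AlphabetError(f"{path}: record {name!r}: {exc}") from exc
        if not seq:
            raise FormatError(f"{path}:{header_line}: empty record {name!r}")
        records.append(LibraryRecord(name=name, role=role, sequence=seq))

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].strip()
                if "|" in head:
                    name, _, role = head.partition("|")
                    name, role = name.strip(), role.strip()
                else:
                    name, role = head, "target"
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty record name")
                if role not in ROLES:
                    raise FormatError(
                        f"{path}:{lineno}: unknown role {role!r} (expected {ROLES})"
                    )
                if (name, role) in seen:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate record ({name!r}, {role!r})"
                    )
                seen.add((name, role))
                header = (name, role)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                try:
                    normalize(line)
                except AlphabetError as exc:
                    raise AlphabetError(f"{path}:{lineno}: {exc}") from exc
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Sequence[LibraryRecord], path: Union[str, Path]) -> None:
    """Write records in input order, wrapped at 60 columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.name}|{rec.role}\n")
            for i in range(0, len(rec.sequence), _FASTA_WRAP):
                fh.write(rec.sequence[i : i + _FASTA_WRAP] + "\n")


def write_matrix_tsv(m: CrosstalkMatrix, path: Union[str, Path]) -> None:
    """TSV matrix: rows = STARs, columns = targets, corner ``star\\target``."""
    df = pd.DataFrame(m.counts, index=list(m.names), columns=list(m.names))
    df.index.name = "star\\target"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: Union[str, Path], metric: str = "mfe_pairs") -> CrosstalkMatrix:
    """Read back a matrix written by :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column names differ")
    return CrosstalkMatrix(
        names=tuple(str(n) for n in df.index),
        counts=df.to_numpy(dtype=np.int64),
        metric=metric,
    )


def load_config(path: Union[str, Path, None]) -> DesignConfig:
    """Load a flat YAML design configuration, applying defaults.

    Unknown keys are errors (they are almost always typos); type
    mismatches and violated bounds raise :class:`ConfigError` naming the
    key.  ``None`` or an empty file yields the full default configuration.
    """
    data: Dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        data = raw
    known = {f.name: f for f in dataclasses.fields(DesignConfig)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    coerced: Dict = {}
    for key, value in data.items():
        f = known[key]
        if key == "forbidden_motifs":
            if not isinstance(value, (list, tuple)) or not all(
                isinstance(v, str) for v in value
            ):
                raise ConfigError(f"config key {key!r}: expected a list of strings")
            coerced[key] = tuple(value)
        elif f.type in ("int", int):
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"config key {key!r}: expected an integer, got {value!r}")
            coerced[key] = value
        elif f.type in ("float", float):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"config key {key!r}: expected a number, got {value!r}")
            coerced[key] = float(value)
        else:
            coerced[key] = value
    try:
        return DesignConfig(**coerced)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_scaffold(path: Union[str, Path]) -> TerminatorScaffold:
    """Load a terminator scaffold from YAML (stem5/loop/u_tract, optional
    name and stem3; stem3 is derived when absent)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ScaffoldError(f"{path}: scaffold file must be a mapping")
    allowed = {"name", "stem5", "loop", "u_tract", "stem3"}
    unknown = set(raw) - allowed
    if unknown:
        raise ScaffoldError(f"{path}: unknown scaffold key(s): {sorted(unknown)}")
    missing = {"stem5", "loop", "u_tract"} - set(raw)
    if missing:
        raise ScaffoldError(f"{path}: missing scaffold key(s): {sorted(missing)}")
    return TerminatorScaffold(
        name=str(raw.get("name", Path(path).stem)),
        stem5=raw["stem5"],
        loop=raw["loop"],
        u_tract=raw["u_tract"],
        stem3=raw.get("stem3", ""),
    )


def write_scaffold(s: TerminatorScaffold, path: Union[str, Path]) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "name": s.name,
                "stem5": s.stem5,
                "loop": s.loop,
                "stem3": s.stem3,
                "u_tract": s.u_tract,
            },
            sort_keys=True,
        )
    )


def write_library(
    designs: Sequence[StarDesign], out_prefix: Union[str, Path]
) -> tuple[Path, Path]:
    """Write a designed library as FASTA + JSON report.

    The FASTA holds two records per design (``name|target`` and
    ``name|star``); the JSON carries the linear regions, the scaffold and
    all score components, enough to rebuild every design exactly.
    """
    out_prefix = Path(out_prefix)
    fasta_path = out_prefix.with_suffix(".fasta")
    json_path = out_prefix.with_suffix(".json")
    records: List[LibraryRecord] = []
    for d in designs:
        records.append(LibraryRecord(name=d.name, role="target", sequence=d.target_seq))
        records.append(LibraryRecord(name=d.name, role="star", sequence=d.star_seq))
    write_fasta(records, fasta_path)
    payload = {
        "scaffold": {
            "name": designs[0].scaffold.name,
            "stem5": designs[0].scaffold.stem5,
            "loop": designs[0].scaffold.loop,
            "stem3": designs[0].scaffold.stem3,
            "u_tract": designs[0].scaffold.u_tract,
        },
        "designs": [
            {
                "name": d.name,
                "linear": d.linear,
                "target": d.target_seq,
                "star": d.star_seq,
                "recognition_len": d.recognition_len,
                "score": d.score.as_dict() if d.score else None,
            }
            for d in designs
        ],
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return fasta_path, json_path


def read_library(json_path: Union[str, Path]) -> List[StarDesign]:
    """Rebuild designs from a library JSON report."""
    payload = json.loads(Path(json_path).read_text())
    sc = payload["scaffold"]
    scaffold = TerminatorScaffold(
        name=sc["name"],
        stem5=sc["stem5"],
        loop=sc["loop"],
        u_tract=sc["u_tract"],
        stem3=sc.get("stem3", ""),
    )
    out: List[StarDesign] = []
    for entry in payload["designs"]:
        d = StarDesign(name=entry["name"], linear=entry["linear"], scaffold=scaffold)
        if d.target_seq != normalize(entry["target"]) or d.star_seq != normalize(
            entry["star"]
        ):
            raise FormatError(
                f"{json_path}: design {entry['name']!r} is inconsistent with its scaffold"
            )
        out.append(d)
    return out
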