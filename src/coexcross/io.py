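"""Plain-text interchange formats.

All pipeline stages communicate through inspectable text files:

* counts TSV — rows are genes, first column ``gene_id``, remaining columns
  are sample ids, integer counts;
* sample metadata TSV — columns ``sample_id``, ``condition`` (case/control),
  ``tissue``;
* gene lists — one symbol per line, ``#`` comments allowed;
* GMT — one gene set per line: name, description, tab-separated members.

Lines starting with ``#`` are treated as comments everywhere, which lets
output tables carry a parameter-recording header without breaking round trips.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

CONDITIONS = ("case", "control")


class FileFormatError(ValueError):
    """A structural problem in an input file (named file and line where known)."""


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count matrix; index = gene_id, columns = samples."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise FileFormatError(f"{path}: first column must be 'gene_id', got '{df.columns[0]}'")
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FileFormatError(f"{path}: duplicate gene ids, e.g. {dups}")
    return df


def write_counts(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_table(df.rename_axis("gene_id").reset_index(), path, header_comment)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata; index = sample_id, columns condition, tissue."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "condition", "tissue"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing required column '{col}'")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise FileFormatError(f"{path}: condition values must be in {CONDITIONS}, got {sorted(bad)}")
    return df.set_index("sample_id")


def write_metadata(df: pd.DataFrame, path) -> None:
    _write_table(df.rename_axis("sample_id").reset_index(), path, None)


def read_gene_list(path) -> set[str]:
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT collection: ``{set_name: (description, member set)}``."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            members = {f for f in fields[2:] if f}
            if name in sets:
                raise FileFormatError(f"{path}:{lineno}: duplicate set name '{name}'")
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def _write_table(df: pd.DataFrame, path, header_comment: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write any result table as TSV with an optional ``#`` parameter header."""
    _write_table(df, path, header_comment)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
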