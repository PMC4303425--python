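"""File I/O for the formats the pipeline exchanges.

FASTA through Bio.SeqIO, tabular data through pandas TSV, gene sets as GMT.
Every table the pipeline writes carries ``#``-prefixed header lines with the
tool version, a hash of the run configuration and the seed, so that outputs
are auditable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{identifier: sequence}`` dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None) -> None:
    """Write a TSV, prefixed with ``# key: value`` header lines from *meta*."""
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_gmt(path, min_size: int | None = None, max_size: int | None = None) -> dict[str, set[str]]:
    """Parse a GMT gene-set file.

    Each line is ``name<TAB>description<TAB>member...``; malformed lines are
    reported with their line number. Optional inclusive size bounds filter
    the returned sets.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, members = fields[0], {m for m in fields[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if min_size is not None and len(members) < min_size:
                continue
            if max_size is not None and len(members) > max_size:
                continue
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def output_meta(config_obj, seed) -> dict[str, object]:
    """Standard header metadata for pipeline output tables."""
    from . import __version__

    return {"tool": f"ptmvar {__version__}", "config_hash": config_hash(config_obj), "seed": seed}
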