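"""File I/O helpers: FASTA in/out, repeat/domain tables, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .motif_scan import DomainAnnotation, RepeatUnit

TSV_COLUMNS = ["seq_id", "start", "end", "element_type", "mode", "score"]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """All records of a (multi-)FASTA file; first header word is the ID."""
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def repeats_to_frame(seq_id: str, repeats: Iterable[RepeatUnit]) -> pd.DataFrame:
    rows = []
    for u in repeats:
        rows.append((seq_id, u.strand_span[0], u.strand_span[1],
                     "strand", u.mode, u.score))
        if u.loop_span is not None:
            rows.append((seq_id, u.loop_span[0], u.loop_span[1],
                         "loop", u.mode, u.score))
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def domains_to_frame(seq_id: str, annotation: DomainAnnotation) -> pd.DataFrame:
    rows = [(seq_id, lo, hi, name, "", "")
            for name, rng in annotation.ranges().items()
            if rng is not None
            for lo, hi in [rng]]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def annotation_to_json(seq_id: str, annotation: DomainAnnotation) -> dict:
    return {
        "seq_id": seq_id,
        "domains": {k: list(v) if v else None
                    for k, v in annotation.ranges().items()},
        "repeats": [
            {"start": u.start, "strand_span": list(u.strand_span),
             "loop_span": list(u.loop_span) if u.loop_span else None,
             "mode": u.mode, "score": u.score}
            for u in annotation.repeats
        ],
        "warning": annotation.warning,
    }


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    try:
        import numpy as np

        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON-serializable: {type(x)}")
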