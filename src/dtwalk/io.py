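"""Readers and writers for the delimited text formats.

Formats:

* interaction edge list — ``drug_id<tab>target_id`` per row, ``#``
  comments allowed; duplicates are dropped with a warning;
* similarity layer — tab-delimited matrix, first row and first column
  are node ids; external layers may declare a source value range (for
  instance ``(0, 2]`` for shape+color combo scores) and are rescaled to
  the unit range on load;
* fingerprint table — ``drug_id<tab>bitstring`` with a 0/1 character per
  feature;
* SMILES list — ``smiles<tab>drug_id`` per line;
* protein sequences — standard FASTA, id taken as the first
  whitespace-delimited header token;
* predictions — ``query_drug<tab>rank<tab>target_id<tab>score`` with
  6-significant-digit scores;
* config — ``key = value`` lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .hetnet import InteractionTable
from .rwr import RankedPrediction
from .similarity import FingerprintTable, SequenceTable, SimilarityLayer

logger = logging.getLogger(__name__)

ASYMMETRY_WARN = 1e-6


@dataclass
class RunConfig:
    """Resolved run configuration: walk parameters, blend weights, paths.

    Exactly one drug-side source (fingerprints, SMILES or a precomputed
    drug-similarity matrix) and one target-side source (FASTA or a
    precomputed target-similarity matrix) must be given for a full run.
    """

    c: float = 0.3
    eta: float = 0.01
    lambda_: float = 0.5
    w_d: float = 0.5
    w_t: float = 0.5
    tol: float = 1e-10
    max_iter: int = 1_000_000
    top_ns: tuple[int, ...] = (10, 25, 50, 100)
    bedroc_alpha: float = 20.0
    ef_fraction: float = 0.1
    rng_seed: int = 0
    interactions: str | None = None
    fingerprints: str | None = None
    smiles: str | None = None
    drug_similarity: str | None = None
    sequences: str | None = None
    target_similarity: str | None = None
    similarity_range: tuple[float, float] = (0.0, 1.0)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = read_config(path)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, str]) -> "RunConfig":
        kwargs: dict = {}
        valid = {f.name for f in fields(cls)} | {"lambda"}
        for key, val in raw.items():
            key = key.strip().replace("-", "_")
            if key == "lambda":
                key = "lambda_"
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = val
        for key in ("c", "eta", "lambda_", "w_d", "w_t", "tol",
                    "bedroc_alpha", "ef_fraction"):
            if key in kwargs:
                kwargs[key] = float(kwargs[key])
        for key in ("max_iter", "rng_seed"):
            if key in kwargs:
                kwargs[key] = int(kwargs[key])
        if "top_ns" in kwargs and isinstance(kwargs["top_ns"], str):
            kwargs["top_ns"] = tuple(
                int(x) for x in kwargs["top_ns"].replace(",", " ").split()
            )
        if "similarity_range" in kwargs and isinstance(
            kwargs["similarity_range"], str
        ):
            lo, hi = kwargs["similarity_range"].replace(",", " ").split()
            kwargs["similarity_range"] = (float(lo), float(hi))
        return cls(**kwargs)


def read_config(path: str | Path) -> dict[str, str]:
    """Parse ``key = value`` lines; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a drug-target edge list.

    Id registries keep first-seen order; duplicate pairs are dropped with
    a warning; a row without exactly two fields fails with its line
    number.
    """
    drug_ids: list[str] = []
    target_ids: list[str] = []
    seen_d: set[str] = set()
    seen_t: set[str] = set()
    links: list[tuple[str, str]] = []
    link_set: set[tuple[str, str]] = set()
    n_dup = 0
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated fields, "
                f"got {len(parts)}"
            )
        d, t = (p.strip() for p in parts)
        if not d or not t:
            raise ValueError(f"{path}:{lineno}: empty id")
        if d not in seen_d:
            seen_d.add(d)
            drug_ids.append(d)
        if t not in seen_t:
            seen_t.add(t)
            target_ids.append(t)
        if (d, t) in link_set:
            n_dup += 1
            continue
        link_set.add((d, t))
        links.append((d, t))
    if n_dup:
        logger.warning("dropped %d duplicate link(s) in %s", n_dup, path)
    if not links:
        logger.warning("no links read from %s", path)
    return InteractionTable(
        drug_ids=tuple(drug_ids),
        target_ids=tuple(target_ids),
        links=frozenset(links),
    )


def write_interactions(
    interactions: InteractionTable, path: str | Path
) -> None:
    lines = [f"{d}\t{t}" for d, t in sorted(interactions.links)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# similarity layers
# ---------------------------------------------------------------------------


def read_similarity(
    path: str | Path,
    declared_range: tuple[float, float] = (0.0, 1.0),
    source: str = "external",
) -> SimilarityLayer:
    """Read a labeled square similarity matrix.

    Values are rescaled linearly from ``declared_range`` to [0, 1] (an
    external shape+color combo layer declares ``(0, 2)``), symmetrized by
    averaging mismatched (i, j)/(j, i) pairs with a warning, and the
    diagonal is forced to exactly 1 with a warning when off by more than
    1e-6.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError(
            f"{path}: row and column labels differ (not a square layer)"
        )
    vals = df.to_numpy(dtype=float)
    lo, hi = declared_range
    if hi <= lo:
        raise ValueError("declared range must have hi > lo")
    if (lo, hi) != (0.0, 1.0):
        vals = (vals - lo) / (hi - lo)
    asym = float(np.max(np.abs(vals - vals.T))) if len(rows) else 0.0
    if asym > ASYMMETRY_WARN:
        logger.warning(
            "%s: asymmetric by up to %.3g; averaging (i,j) and (j,i)",
            path,
            asym,
        )
    vals = (vals + vals.T) / 2.0
    diag_dev = float(np.max(np.abs(np.diag(vals) - 1.0))) if len(rows) else 0.0
    if diag_dev > ASYMMETRY_WARN:
        logger.warning(
            "%s: diagonal off unity by up to %.3g; forcing to 1", path, diag_dev
        )
    np.fill_diagonal(vals, 1.0)
    vals = np.clip(vals, 0.0, 1.0)
    return SimilarityLayer(ids=tuple(rows), values=vals, source=source)


def write_similarity(layer: SimilarityLayer, path: str | Path) -> None:
    df = pd.DataFrame(layer.values, index=layer.ids, columns=layer.ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# fingerprints / SMILES / sequences
# ---------------------------------------------------------------------------


def read_fingerprints(
    path: str | Path, family: str = "EXTERNAL"
) -> FingerprintTable:
    """Read ``drug_id<tab>bitstring`` rows into a fingerprint table."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    width: int | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 'drug_id<tab>bitstring'"
            )
        did, bitstr = parts[0].strip(), parts[1].strip()
        if set(bitstr) - {"0", "1"}:
            raise ValueError(f"{path}:{lineno}: bitstring must be 0/1")
        if width is None:
            width = len(bitstr)
        elif len(bitstr) != width:
            raise ValueError(
                f"{path}:{lineno}: bitstring width {len(bitstr)} != {width}"
            )
        ids.append(did)
        rows.append(np.frombuffer(bitstr.encode(), dtype=np.uint8) == ord("1"))
    if not rows:
        raise ValueError(f"{path}: no fingerprint rows")
    return FingerprintTable(
        ids=tuple(ids), bits=np.vstack(rows), family=family
    )


def write_fingerprints(fp: FingerprintTable, path: str | Path) -> None:
    lines = [
        f"{did}\t" + "".join("1" if b else "0" for b in row)
        for did, row in zip(fp.ids, fp.bits)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_smiles(path: str | Path) -> list[tuple[str, str]]:
    """Read ``smiles<tab>drug_id`` lines; returns (smiles, id) pairs."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'smiles<tab>drug_id'")
        out.append((parts[0].strip(), parts[1].strip()))
    return out


def read_sequences(path: str | Path) -> SequenceTable:
    """Read protein sequences from FASTA (Biopython dialect)."""
    from Bio import SeqIO

    ids: list[str] = []
    residues: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        residues.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceTable(ids=tuple(ids), residues=tuple(residues))


def write_fasta(seqs: SequenceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, seq in zip(seqs.ids, seqs.residues):
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_predictions(
    predictions: Mapping[str, RankedPrediction],
    out: TextIO | str | Path,
    top: int | None = None,
) -> None:
    """Write ranked predictions as ``drug<tab>rank<tab>target<tab>score``."""
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w")
        close = True
    try:
        out.write("query_drug\trank\ttarget_id\tscore\n")
        for drug in predictions:
            pred = predictions[drug]
            n = len(pred.targets) if top is None else min(top, len(pred.targets))
            for i in range(n):
                out.write(
                    f"{drug}\t{i + 1}\t{pred.targets[i]}\t"
                    f"{pred.scores[i]:.6g}\n"
                )
    finally:
        if close:
            out.close()


def write_removal_records(records, out: TextIO | str | Path) -> None:
    """Export removal records as ``drug<tab>target<tab>rank<tab>n_candidates``."""
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w")
        close = True
    try:
        out.write("drug\ttarget\trank\tn_candidates\n")
        for r in records:
            out.write(f"{r.drug}\t{r.target}\t{r.rank}\t{r.n_candidates}\n")
    finally:
        if close:
            out.close()


def write_metrics(
    reports: Mapping[str, "object"], out: TextIO | str | Path
) -> None:
    """Write one row per labelled :class:`MetricsReport`."""
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w")
        close = True
    try:
        labels = list(reports)
        columns: list[str] = []
        rows = {}
        for label in labels:
            d = reports[label].as_dict()
            rows[label] = d
            for k in d:
                if k not in columns:
                    columns.append(k)
        out.write("protocol\t" + "\t".join(columns) + "\n")
        for label in labels:
            vals = [
                f"{rows[label][k]:.6g}" if k in rows[label] else ""
                for k in columns
            ]
            out.write(label + "\t" + "\t".join(vals) + "\n")
    finally:
        if close:
            out.close()
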