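"""Tab-delimited persistence for expression matrices, databases and annotations.

The on-disk database is a directory of plain TSV tables mirroring the
logical schema: ``contrasts.tsv`` (metadata), ``fold.tsv`` and
``pvalue.tsv`` (probe × contrast matrices), plus one TSV per annotation
table.  Missing values are the literal token ``NA``; floats are written
with shortest round-trip precision so save → load is exact.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnnotationSet,
    ContrastDatabase,
    ContrastRecord,
    ExpressionMatrix,
    FormatError,
    GroupDefinition,
    LoadError,
    Signature,
    ValidationError,
)

NA = "NA"

CONTRASTS_TSV = "contrasts.tsv"
FOLD_TSV = "fold.tsv"
PVALUE_TSV = "pvalue.tsv"
GO_TSV = "go.tsv"
GO2PROBE_TSV = "go2probe.tsv"
GENBANK2UNIGENE_TSV = "genbank2unigene.tsv"
UNIGENE2PROBE_TSV = "unigene2probe.tsv"
TITLES_TSV = "titles.tsv"

ANNOTATION_FILES = (GO_TSV, GO2PROBE_TSV, GENBANK2UNIGENE_TSV, UNIGENE2PROBE_TSV, TITLES_TSV)


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return NA
    return repr(float(x))


def _parse_float(tok: str, where: str) -> float:
    if tok == NA or tok == "":
        return math.nan
    try:
        return float(tok)
    except ValueError:
        raise FormatError(f"{where}: cannot parse {tok!r} as a number")


def _read_rows(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                rows.append(line.split("\t"))
    return rows


# ---------------------------------------------------------------------------
# expression matrices and group definitions

def load_expression_matrix(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Read a probe × sample TSV (header row = sample IDs, first column = probe IDs)."""
    rows = _read_rows(path)
    if not rows or len(rows[0]) < 2:
        raise FormatError(f"{path}: expected a header row with at least one sample column")
    header = rows[0]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample ID in header")
    probe_ids, data = [], []
    for r in rows[1:]:
        if len(r) != len(header):
            raise FormatError(f"{path}: row for {r[0]!r} has {len(r)} fields, expected {len(header)}")
        probe_ids.append(r[0])
        data.append([_parse_float(t, f"{path}:{r[0]}") for t in r[1:]])
    values = np.array(data, dtype=float) if data else np.empty((0, len(sample_ids)))
    experiment_id = Path(path).stem
    return ExpressionMatrix(probe_ids, sample_ids, values, experiment_id=experiment_id, scale=scale)


def save_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, pid in enumerate(matrix.probe_ids):
            fh.write(pid + "\t" + "\t".join(_fmt(v) for v in matrix.values[i]) + "\n")


def load_group_definitions(path: str | Path) -> list[GroupDefinition]:
    """Read contrast group assignments.

    Data rows are ``contrast_id<TAB>sample_id<TAB>group`` with group in
    {control, treated}; an optional comment line
    ``# description:<TAB>contrast_id<TAB>text`` attaches free text to a
    contrast.  A header row is recognised and skipped.
    """
    descriptions: dict[str, str] = {}
    members: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("description:"):
                    parts = body[len("description:"):].strip().split("\t", 1)
                    if len(parts) == 2:
                        descriptions[parts[0]] = parts[1]
                continue
            fields = line.split("\t")
            if fields[:3] == ["contrast_id", "sample_id", "group"]:
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected contrast_id<TAB>sample_id<TAB>group")
            cid, sid, group = fields[0], fields[1], fields[2]
            if group not in ("control", "treated"):
                raise FormatError(f"{path}:{lineno}: group must be 'control' or 'treated', got {group!r}")
            if cid not in members:
                members[cid] = {"control": [], "treated": []}
                order.append(cid)
            members[cid][group].append(sid)
    return [
        GroupDefinition(
            contrast_id=cid,
            control_samples=members[cid]["control"],
            treated_samples=members[cid]["treated"],
            description=descriptions.get(cid, ""),
        )
        for cid in order
    ]


def save_group_definitions(groups: list[GroupDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("contrast_id\tsample_id\tgroup\n")
        for g in groups:
            if g.description:
                fh.write(f"# description:\t{g.contrast_id}\t{g.description}\n")
            for s in g.control_samples:
                fh.write(f"{g.contrast_id}\t{s}\tcontrol\n")
            for s in g.treated_samples:
                fh.write(f"{g.contrast_id}\t{s}\ttreated\n")


# ---------------------------------------------------------------------------
# signatures

def load_signature(path: str | Path) -> Signature:
    """Read a ``probe_id<TAB>fold_change`` table; a header row is auto-detected."""
    rows = _read_rows(path)
    entries: list[tuple[str, float]] = []
    for i, r in enumerate(rows):
        if len(r) < 2:
            raise FormatError(f"{path}: row {i + 1} needs two tab-separated fields")
        if i == 0:
            try:
                float(r[1].replace("−", "-"))
            except ValueError:
                continue  # header row
        # tolerate the typographic minus that appears in published tables
        entries.append((r[0], float(r[1].replace("−", "-"))))
    return Signature(entries)


def save_signature(sig: Signature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tfold_change\n")
        for pid, f in sig.entries:
            fh.write(f"{pid}\t{_fmt(f)}\n")


# ---------------------------------------------------------------------------
# annotations

def _check_header(rows: list[list[str]], expected: tuple[str, ...], path) -> list[list[str]]:
    if not rows:
        raise FormatError(f"{path}: empty annotation table (header row required)")
    header = [h.strip() for h in rows[0][: len(expected)]]
    if header != list(expected):
        raise FormatError(f"{path}: expected columns {expected}, found {tuple(rows[0])}")
    return rows[1:]


def _parse_go_id(tok: str, where: str) -> int:
    tok = tok.strip()
    if tok.upper().startswith("GO:"):
        tok = tok[3:]
    try:
        return int(tok)
    except ValueError:
        raise FormatError(f"{where}: cannot parse GO id {tok!r}")


def load_annotations(
    go: str | Path | None = None,
    go2probe: str | Path | None = None,
    genbank2unigene: str | Path | None = None,
    unigene2probe: str | Path | None = None,
    titles: str | Path | None = None,
) -> AnnotationSet:
    """Assemble an AnnotationSet from individual TSV tables (each optional)."""
    ann = AnnotationSet()
    if go is not None:
        for r in _check_header(_read_rows(go), ("go_id", "category"), go):
            gid = _parse_go_id(r[0], go)
            if gid in ann.go_terms:
                raise FormatError(f"{go}: duplicate GO id {gid}")
            ann.go_terms[gid] = r[1] if len(r) > 1 else ""
    if go2probe is not None:
        for r in _check_header(_read_rows(go2probe), ("go_id", "probe_id"), go2probe):
            gid = _parse_go_id(r[0], go2probe)
            ann.go2probe.setdefault(gid, set()).add(r[1])
    if genbank2unigene is not None:
        for r in _check_header(
            _read_rows(genbank2unigene), ("genbank_id", "unigene_id"), genbank2unigene
        ):
            if r[0] in ann.genbank2unigene:
                raise FormatError(f"{genbank2unigene}: duplicate GenBank id {r[0]!r}")
            ann.genbank2unigene[r[0]] = r[1]
    if unigene2probe is not None:
        for r in _check_header(_read_rows(unigene2probe), ("unigene_id", "probe_id"), unigene2probe):
            ann.unigene2probe.setdefault(r[0], set()).add(r[1])
    if titles is not None:
        for r in _check_header(_read_rows(titles), ("probe_id", "title"), titles):
            ann.probe_titles[r[0]] = r[1] if len(r) > 1 else ""
    return ann


def load_annotations_dir(directory: str | Path) -> AnnotationSet:
    d = Path(directory)

    def maybe(name):
        p = d / name
        return p if p.exists() else None

    return load_annotations(
        go=maybe(GO_TSV),
        go2probe=maybe(GO2PROBE_TSV),
        genbank2unigene=maybe(GENBANK2UNIGENE_TSV),
        unigene2probe=maybe(UNIGENE2PROBE_TSV),
        titles=maybe(TITLES_TSV),
    )


def save_annotations(ann: AnnotationSet, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / GO_TSV, "w", encoding="utf-8") as fh:
        fh.write("go_id\tcategory\n")
        for gid in sorted(ann.go_terms):
            fh.write(f"{gid}\t{ann.go_terms[gid]}\n")
    with open(d / GO2PROBE_TSV, "w", encoding="utf-8") as fh:
        fh.write("go_id\tprobe_id\n")
        for gid in sorted(ann.go2probe):
            for pid in sorted(ann.go2probe[gid]):
                fh.write(f"{gid}\t{pid}\n")
    with open(d / GENBANK2UNIGENE_TSV, "w", encoding="utf-8") as fh:
        fh.write("genbank_id\tunigene_id\n")
        for gb in sorted(ann.genbank2unigene):
            fh.write(f"{gb}\t{ann.genbank2unigene[gb]}\n")
    with open(d / UNIGENE2PROBE_TSV, "w", encoding="utf-8") as fh:
        fh.write("unigene_id\tprobe_id\n")
        for ug in sorted(ann.unigene2probe):
            for pid in sorted(ann.unigene2probe[ug]):
                fh.write(f"{ug}\t{pid}\n")
    with open(d / TITLES_TSV, "w", encoding="utf-8") as fh:
        fh.write("probe_id\ttitle\n")
        for pid in sorted(ann.probe_titles):
            fh.write(f"{pid}\t{ann.probe_titles[pid]}\n")


# ---------------------------------------------------------------------------
# database

def _save_value_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["probe_id", *df.columns]) + "\n")
        values = df.to_numpy()
        for i, pid in enumerate(df.index):
            fh.write("\t".join([str(pid), *(_fmt(v) for v in values[i])]) + "\n")


def _load_value_table(path: Path) -> pd.DataFrame:
    rows = _read_rows(path)
    if not rows:
        raise LoadError(f"{path}: empty table")
    header = rows[0]
    cols = header[1:]
    index, data = [], []
    for r in rows[1:]:
        index.append(r[0])
        data.append([_parse_float(t, f"{path}:{r[0]}") for t in r[1:]])
    values = np.array(data, dtype=float) if data else np.empty((0, len(cols)))
    return pd.DataFrame(values, index=pd.Index(index, name="probe_id"), columns=cols)


def save_database(db: ContrastDatabase, path: str | Path) -> None:
    """Write the database directory: metadata, fold/p-value matrices, annotations."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / CONTRASTS_TSV, "w", encoding="utf-8") as fh:
        fh.write("contrast_id\tstudy_title\tn_control\tn_treated\tdesign\n")
        for cid, rec in db.records.items():
            fh.write(
                f"{cid}\t{rec.study_title}\t{rec.n_control}\t{rec.n_treated}\t{rec.design}\n"
            )
    _save_value_table(db.fold_table, d / FOLD_TSV)
    _save_value_table(db.pvalue_table, d / PVALUE_TSV)
    save_annotations(db.annotations, d)


def load_database(path: str | Path) -> ContrastDatabase:
    d = Path(path)
    for name in (CONTRASTS_TSV, FOLD_TSV, PVALUE_TSV):
        if not (d / name).exists():
            raise LoadError(f"database at {d} is missing required table {name}")
    meta_rows = _read_rows(d / CONTRASTS_TSV)
    meta = _check_header(
        meta_rows, ("contrast_id", "study_title", "n_control", "n_treated", "design"), d / CONTRASTS_TSV
    )
    fold = _load_value_table(d / FOLD_TSV)
    pvalue = _load_value_table(d / PVALUE_TSV)
    if list(fold.columns) != [r[0] for r in meta] or list(fold.columns) != list(pvalue.columns):
        raise LoadError(f"database at {d}: contrast ids disagree across tables")
    if not fold.index.equals(pvalue.index):
        raise LoadError(f"database at {d}: fold and p-value tables index different probes")
    db = ContrastDatabase(annotations=load_annotations_dir(d))
    for r in meta:
        cid = r[0]
        rec = ContrastRecord(
            contrast_id=cid,
            study_title=r[1],
            n_control=int(r[2]),
            n_treated=int(r[3]),
            design=r[4] if len(r) > 4 else "",
            fold=fold[cid],
            pvalue=pvalue[cid],
        )
        db.add_contrast(rec)
    db.annotations.flag_unknown(db.probe_universe)
    return db
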