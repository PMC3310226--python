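"""Seeded generators for every input the engine consumes.

Two levels:

* ``simulate_experiment`` emulates a gcrma-normalized microarray
  experiment — per-probe log2 baselines ~ N(8, 2^2), i.i.d. Gaussian array
  noise, and optional planted log2 effects on the treated samples of chosen
  contrasts;
* ``make_demo_fixtures`` writes a complete worked-example bundle: a query
  signature of ten probes with large published-style fold changes, four
  defense-response GO rows, a GenBank→Unigene→probe translation chain, a
  gene-title table, and a synthetic contrast database in which one contrast
  reproduces the query signature exactly (so a self-query correlates at
  r = 1).

All randomness flows from a master seed through fixed stream offsets, so
adding one artifact never perturbs another and outputs are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dbio
from .core import (
    AnnotationSet,
    ContrastDatabase,
    ContrastRecord,
    ExpressionMatrix,
    GroupDefinition,
    Signature,
    ValidationError,
)

# fixed per-artifact stream offsets under the master seed
_STREAM_MATRIX = 1
_STREAM_FOLDS = 2
_STREAM_PVALUES = 3
_STREAM_DEMO = 4


@dataclass
class PlantedEffect:
    """A block of probes shifted by ``effect`` log2 units in one contrast's treated arrays."""

    probe_indices: list[int]
    effect: float
    contrast_index: int = 0


@dataclass
class SimConfig:
    seed: int = 0
    n_probes: int = 1000
    n_contrasts: int = 1
    n_control: int = 3
    n_treated: int = 3
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    planted: list[PlantedEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_treated < 2:
            raise ValidationError("group sizes must be >= 2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for pe in self.planted:
            if not np.isfinite(pe.effect):
                raise ValidationError("planted effect sizes must be finite")
            if not (0 <= pe.contrast_index < self.n_contrasts):
                raise ValidationError(f"planted contrast index {pe.contrast_index} out of range")
            if any(i < 0 or i >= self.n_probes for i in pe.probe_indices):
                raise ValidationError("planted probe index out of range")


def _probe_ids(n: int) -> list[str]:
    return [f"{200000 + i}_at" for i in range(n)]


def simulate_experiment(cfg: SimConfig) -> tuple[ExpressionMatrix, list[GroupDefinition]]:
    """One log2-scale experiment with ``n_contrasts`` disjoint sample groups.

    Contrast *k* owns its own block of control+treated arrays; planted
    effects are added to the treated arrays of their designated contrast.
    """
    rng = np.random.default_rng([int(cfg.seed), _STREAM_MATRIX])
    per_contrast = cfg.n_control + cfg.n_treated
    n_samples = per_contrast * cfg.n_contrasts
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_probes)
    values = np.repeat(baseline[:, None], n_samples, axis=1)
    if cfg.noise_sd > 0:
        values += rng.normal(0.0, cfg.noise_sd, size=(cfg.n_probes, n_samples))
    sample_ids = [f"GSM{100001 + j}" for j in range(n_samples)]
    experiment_id = f"SYN{int(cfg.seed) % 100000:05d}"
    groups = []
    for k in range(cfg.n_contrasts):
        lo = k * per_contrast
        groups.append(
            GroupDefinition(
                contrast_id=f"{experiment_id}_{k + 1}",
                control_samples=sample_ids[lo : lo + cfg.n_control],
                treated_samples=sample_ids[lo + cfg.n_control : lo + per_contrast],
                description=f"synthetic control versus treated, block {k + 1}",
            )
        )
    for pe in cfg.planted:
        g = groups[pe.contrast_index]
        cols = [sample_ids.index(s) for s in g.treated_samples]
        values[np.ix_(pe.probe_indices, cols)] += pe.effect
    matrix = ExpressionMatrix(
        probe_ids=_probe_ids(cfg.n_probes),
        sample_ids=sample_ids,
        values=values,
        experiment_id=experiment_id,
        scale="log2",
    )
    return matrix, groups


def simulate_fold_database(
    seed: int,
    n_probes: int = 300,
    n_contrasts: int = 200,
    fold_sd: float = 0.5,
    planted: list[PlantedEffect] | None = None,
    probe_ids: list[str] | None = None,
    annotations: AnnotationSet | None = None,
) -> ContrastDatabase:
    """A contrast database with i.i.d. Normal(0, fold_sd^2) fold values.

    This skips the per-array simulation and draws the per-contrast fold
    vectors directly — the right null model for search-level tests, where
    only the stored summaries matter.  ``planted`` shifts blocks of probes
    in chosen contrasts.  Stored p-values are Uniform(0, 1] placeholders.
    """
    rng_f = np.random.default_rng([int(seed), _STREAM_FOLDS])
    rng_p = np.random.default_rng([int(seed), _STREAM_PVALUES])
    pids = list(probe_ids) if probe_ids is not None else _probe_ids(n_probes)
    if len(pids) != n_probes:
        raise ValidationError("probe_ids length must equal n_probes")
    folds = rng_f.normal(0.0, fold_sd, size=(n_probes, n_contrasts))
    for pe in planted or []:
        folds[pe.probe_indices, pe.contrast_index] += pe.effect
    pvals = 1.0 - rng_p.random(size=(n_probes, n_contrasts))  # in (0, 1]
    db = ContrastDatabase(annotations=annotations)
    index = pd.Index(pids, name="probe_id")
    for j in range(n_contrasts):
        cid = f"SYN{j + 1:05d}_1"
        db.add_contrast(
            ContrastRecord(
                contrast_id=cid,
                study_title=f"synthetic null contrast {j + 1}",
                n_control=3,
                n_treated=3,
                design="simulated",
                fold=pd.Series(folds[:, j], index=index),
                pvalue=pd.Series(pvals[:, j], index=index),
            )
        )
    return db


# ---------------------------------------------------------------------------
# worked-example fixture bundle

#: ten-probe query signature: the largest up/down log2 fold changes from a
#: salt-stress root experiment (the classic worked example for this search)
SIGNATURE_ENTRIES: list[tuple[str, float]] = [
    ("264612_at", -7.454),
    ("260203_at", -7.389),
    ("250648_at", -6.247),
    ("263231_at", -6.239),
    ("248844_s_at", 5.912),
    ("265066_at", 5.652),
    ("254820_s_at", 5.64),
    ("248337_at", -5.624),
    ("264953_at", -5.6),
    ("261077_at", -5.547),
]

#: GO rows returned by a "defense response" category search
GO_TERMS: dict[int, str] = {
    6952: "Defense response inferred from reviewed computational analysis",
    42742: "Defense response to bacterium inferred from mutant phenotype",
    9816: "Defense response to bacterium, incompatible interaction inferred from mutant phenotype",
    9870: "Defense response signalling pathway, resistance gene-dependent inferred from mutant phenotype",
}

#: gene titles matched by a "Cold" title search
TITLE_ROWS: dict[str, str] = {
    "246251_at": "Cold acclimation protein homolog...",
    "246481_s_at": "Cold and ABA inducible protein kin1",
    "247700_at": "RNA-binding protein-like cold-inducible RNA-binding...",
    "249966_at": "putative protein COLD-INDUCIBLE RNA-BINDING PROTEIN",
}

#: GenBank IDs of the worked translation example
GENBANK_IDS: list[str] = ["BP799393", "DR371397", "ES108934", "ES014211"]

#: twelve-probe gene-list query of the worked probe-list example
PROBE_LIST: list[str] = [
    "260130_s_at", "254889_at", "266353_at", "250500_at", "253667_at", "259813_at",
    "260668_at", "251065_at", "253024_at", "267121_at", "247333_at", "252882_at",
]

#: id of the demo contrast that stores the query signature exactly
EMBEDDED_CONTRAST_ID = "EMB0001_1"


def demo_annotations(probe_universe: list[str]) -> AnnotationSet:
    """Annotation tables wired to the demo probe universe."""
    ann = AnnotationSet()
    ann.go_terms = dict(GO_TERMS)
    pool = [p for p in probe_universe]
    # 6952 gets 12 probes so GO-driven heat maps exercise the 10-row cap
    ann.go2probe = {
        6952: set(pool[0:12]),
        42742: set(pool[12:17]),
        9816: set(pool[17:21]),
        9870: set(pool[21:24]),
    }
    ann.genbank2unigene = {gb: f"At.{10001 + i}" for i, gb in enumerate(GENBANK_IDS)}
    ann.unigene2probe = {
        f"At.{10001 + i}": {pool[24 + i]} for i in range(len(GENBANK_IDS))
    }
    ann.probe_titles = dict(TITLE_ROWS)
    return ann


def make_demo_fixtures(outdir: str | Path, seed: int = 0, n_contrasts: int = 40) -> dict[str, Path]:
    """Write the complete worked-example input bundle into ``outdir``.

    Produces signature.tsv, probelist.tsv, the five annotation TSVs and a
    synthetic database directory ``db/`` of ``n_contrasts`` contrasts over
    200 probes.  One contrast stores the signature fold values exactly, so
    querying the bundle with its own signature returns that contrast at
    Pearson r = 1.  Returns the paths keyed by artifact name.
    """
    if n_contrasts < 31:
        raise ValidationError("demo database needs >= 31 contrasts for a full top-30 ranking")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([int(seed), _STREAM_DEMO])

    sig = Signature(SIGNATURE_ENTRIES)
    named = (
        sig.probe_ids
        + list(TITLE_ROWS)
        + PROBE_LIST
    )
    n_probes = 200
    filler = [f"{250000 + i}_syn_at" for i in range(n_probes - len(named))]
    probe_ids = named + filler
    index = pd.Index(probe_ids, name="probe_id")

    ann = demo_annotations(probe_ids)
    db = ContrastDatabase(annotations=ann)
    for j in range(n_contrasts):
        fold = rng.normal(0.0, 0.8, size=n_probes)
        pval = 1.0 - rng.random(size=n_probes)
        if j == 0:
            cid, title = EMBEDDED_CONTRAST_ID, "Root cell-type salt response (embedded query signature)"
            fold[: len(sig)] = sig.folds
        else:
            cid, title = f"SYN{10000 + j}_1", f"synthetic background contrast {j}"
        db.add_contrast(
            ContrastRecord(
                contrast_id=cid,
                study_title=title,
                n_control=3,
                n_treated=3,
                design="simulated",
                fold=pd.Series(fold, index=index),
                pvalue=pd.Series(pval, index=index),
            )
        )
    db.annotations.flag_unknown(db.probe_universe)

    paths: dict[str, Path] = {}
    paths["signature"] = out / "signature.tsv"
    dbio.save_signature(sig, paths["signature"])
    paths["probelist"] = out / "probelist.tsv"
    with open(paths["probelist"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(PROBE_LIST) + "\n")
    paths["genbank"] = out / "genbank_ids.tsv"
    with open(paths["genbank"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(GENBANK_IDS) + "\n")
    dbio.save_annotations(ann, out)
    for key, name in (
        ("go", dbio.GO_TSV),
        ("go2probe", dbio.GO2PROBE_TSV),
        ("genbank2unigene", dbio.GENBANK2UNIGENE_TSV),
        ("unigene2probe", dbio.UNIGENE2PROBE_TSV),
        ("titles", dbio.TITLES_TSV),
    ):
        paths[key] = out / name
    paths["db"] = out / "db"
    dbio.save_database(db, paths["db"])
    return paths
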