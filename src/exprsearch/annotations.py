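"""Non-statistical lookups: GO categories, gene titles, GenBank translation.

All searches are pure functions of (query, AnnotationSet).  Substring
matching is case-insensitive and literal — no stemming, no regex — so
"Cold" and "cold" retrieve the same titles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AnnotationSet, EmptyResultError, NotFoundError, ValidationError


@dataclass
class GoMatch:
    go_id: int
    category: str


@dataclass
class TitleMatch:
    probe_id: str
    gene_title: str


def _clean_term(term: str) -> str:
    term = term.strip()
    if not term:
        raise ValidationError("search term must be non-empty")
    return term.lower()


def go_search(term: str, ann: AnnotationSet) -> list[GoMatch]:
    """GO terms whose category text contains the term, sorted by GO id."""
    needle = _clean_term(term)
    matches = [
        GoMatch(go_id=gid, category=cat)
        for gid, cat in ann.go_terms.items()
        if needle in cat.lower()
    ]
    matches.sort(key=lambda m: m.go_id)
    return matches


def go_probes(go_id: int, ann: AnnotationSet) -> set[str]:
    """Probe IDs annotated to a GO id.

    Distinguishes an unknown id from a known term with no probe mapping.
    """
    go_id = int(go_id)
    if go_id not in ann.go2probe:
        if go_id in ann.go_terms:
            raise NotFoundError(f"GO id {go_id} has no probes mapped to it")
        raise NotFoundError(f"no such GO id: {go_id}")
    return set(ann.go2probe[go_id])


def title_search(term: str, ann: AnnotationSet) -> list[TitleMatch]:
    """Probes whose gene title contains the term, sorted by probe id."""
    needle = _clean_term(term)
    matches = [
        TitleMatch(probe_id=pid, gene_title=title)
        for pid, title in ann.probe_titles.items()
        if needle in title.lower()
    ]
    matches.sort(key=lambda m: m.probe_id)
    return matches


def genbank_to_probes(genbank_ids: list[str], ann: AnnotationSet) -> tuple[set[str], list[str]]:
    """Translate GenBank IDs to probe IDs via the Unigene hop.

    Returns (probe set, unmapped IDs in input order).  An ID fails if either
    hop — GenBank→Unigene or Unigene→probe — is missing; failures are
    reported, never silently dropped.  Raises if every ID is unmapped.
    """
    ids = [str(g).strip() for g in genbank_ids if str(g).strip()]
    if not ids:
        raise ValidationError("at least one GenBank ID is required")
    probes: set[str] = set()
    unmapped: list[str] = []
    for gb in ids:
        unigene = ann.genbank2unigene.get(gb)
        hit = ann.unigene2probe.get(unigene) if unigene is not None else None
        if hit:
            probes |= hit
        else:
            unmapped.append(gb)
    if not probes:
        raise EmptyResultError(
            f"none of the {len(ids)} GenBank IDs could be mapped to probes",
            unmatched=unmapped,
        )
    return probes, unmapped
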