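"""Marker-based discovery of new Borg-like genomes in assemblies.

A bin (or contig set) is scored by how many of the reference marker
subfamilies (40 single-copy markers by default) have a confident homolog
among its proteins; bins reaching at least 60% of the marker set are
accepted as candidate Borgs. Candidate contigs can additionally be filtered
by GC window, coverage window and dominance of taxonomically unclassified
proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .pangenome import _make_aligner, _kmers, bit_score

DEFAULT_MIN_BITSCORE = 50.0
DEFAULT_MIN_COVER = 0.5
DEFAULT_MIN_FRACTION = 0.6


@dataclass
class MarkerHitTable:
    """Per-bin marker hits: hits[bin][marker] = [(bit score, protein id), ...]
    sorted best-first; every listed hit already passed the score filter."""

    hits: dict[str, dict[str, list[tuple[float, str]]]]
    marker_ids: list[str]

    def markers_found(self, bin_id: str) -> int:
        return len(self.hits.get(bin_id, {}))

    def fraction(self, bin_id: str) -> float:
        return self.markers_found(bin_id) / len(self.marker_ids)

    def duplicated(self, bin_id: str) -> list[str]:
        return sorted(m for m, hs in self.hits.get(bin_id, {}).items()
                      if len(hs) >= 2)


def find_marker_hits(bin_proteins: dict[str, dict[str, str]],
                     marker_refs: dict[str, str],
                     min_score: float = DEFAULT_MIN_BITSCORE,
                     min_cover: float = DEFAULT_MIN_COVER,
                     k: int = 5, min_shared_kmers: int = 2) -> MarkerHitTable:
    """Search each bin's proteins against the marker reference set.

    ``bin_proteins`` maps bin (or contig) id -> {protein id: sequence}. Hits
    are local alignments with bit score >= min_score covering >= min_cover of
    the shorter sequence; a k-mer prefilter skips unrelated pairs.
    """
    if not marker_refs:
        raise ValueError("marker reference set is empty")
    aligner = _make_aligner()
    marker_kmers = {m: _kmers(s.upper(), k) for m, s in marker_refs.items()}
    hits: dict[str, dict[str, list[tuple[float, str]]]] = {}
    for bin_id, prots in bin_proteins.items():
        if not prots:
            warnings.warn(f"bin {bin_id} has no proteins")
            hits[bin_id] = {}
            continue
        per_marker: dict[str, list[tuple[float, str]]] = {}
        for pid, seq in prots.items():
            seq = seq.upper()
            kms = _kmers(seq, k)
            for m, ref in marker_refs.items():
                if len(kms & marker_kmers[m]) < min_shared_kmers:
                    continue
                aln = aligner.align(seq, ref.upper())[0]
                bits = bit_score(aln.score)
                if bits < min_score:
                    continue
                spans = aln.aligned
                short_idx = 0 if len(seq) <= len(ref) else 1
                cov = sum(e - s for s, e in spans[short_idx]) / min(len(seq), len(ref))
                if cov < min_cover:
                    continue
                per_marker.setdefault(m, []).append((bits, pid))
        for m in per_marker:
            per_marker[m].sort(key=lambda t: (-t[0], t[1]))
        hits[bin_id] = per_marker
    return MarkerHitTable(hits=hits, marker_ids=sorted(marker_refs))


def score_bins(hits: MarkerHitTable,
               min_fraction: float = DEFAULT_MIN_FRACTION) -> pd.DataFrame:
    """Accept bins whose marker fraction reaches ``min_fraction`` (inclusive)."""
    rows = []
    for bin_id in sorted(hits.hits):
        frac = hits.fraction(bin_id)
        rows.append({
            "bin": bin_id,
            "markers_found": hits.markers_found(bin_id),
            "marker_set_size": len(hits.marker_ids),
            "fraction": frac,
            "duplicated": ",".join(hits.duplicated(bin_id)),
            "accepted": frac >= min_fraction,
        })
    return pd.DataFrame(rows)


def filter_candidate_contigs(contigs: pd.DataFrame,
                             gc_range: Optional[tuple[float, float]] = None,
                             cov_range: Optional[tuple[float, float]] = None,
                             max_classified_fraction: Optional[float] = None
                             ) -> pd.DataFrame:
    """Keep contigs inside the GC and coverage windows with a classified
    protein fraction at most ``max_classified_fraction``. Passing ``None``
    disables the corresponding filter. Requires columns ``gc``, ``coverage``
    and ``classified_fraction``.
    """
    if "coverage" not in contigs.columns:
        raise ValueError("missing coverage column")
    for col in ("gc", "classified_fraction"):
        if col not in contigs.columns:
            raise ValueError(f"missing {col} column")
    keep = pd.Series(True, index=contigs.index)
    if gc_range is not None:
        keep &= contigs["gc"].between(*gc_range)
    if cov_range is not None:
        keep &= contigs["coverage"].between(*cov_range)
    if max_classified_fraction is not None:
        keep &= contigs["classified_fraction"] <= max_classified_fraction
    return contigs[keep]


def unclassified_percent(n_unclassified: int, n_total: int) -> int:
    """Whole-percent share of proteins without taxonomic affiliation."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_unclassified / n_total)


__all__ = ["MarkerHitTable", "find_marker_hits", "score_bins",
           "filter_candidate_contigs", "unclassified_percent"]
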