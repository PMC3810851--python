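"""Alignment of summary-statistic records to reference-panel variants.

Imputation requires the typed Z-scores and the LD matrix to share one allele
orientation.  The canonical orientation is the panel's: after harmonisation a
positive Z always means the panel *alt* allele increases the trait.  Records
whose effect allele is the panel ref allele get their Z negated; records on
the opposite strand are reverse-complemented first; A/T and C/G SNPs are
strand-ambiguous (their reverse complement equals an allele swap) and are
dropped by default.  Panel variants with no matching record become the
imputation targets.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import ReferencePanel
from .sumstats import SumStatRecord

log = logging.getLogger(__name__)

FLIP_NONE = "none"
FLIP_SWAP = "allele_swap"
FLIP_STRAND = "strand_flip"
FLIP_STRAND_SWAP = "strand_flip+swap"
DROP_AMBIGUOUS = "dropped_ambiguous"
DROP_MISMATCH = "dropped_mismatch"

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


def _revcomp(allele: str) -> str:
    return _COMP[allele]


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G SNPs cannot be strand-resolved from alleles alone."""
    return {a1, a2} in _AMBIGUOUS_PAIRS


@dataclass
class HarmonizedSet:
    """Summary statistics aligned to panel variants.

    ``z[i]`` is finite iff ``typed_mask[i]``; ``flips[i]`` records the
    transformation applied to the matching record (or why it was dropped);
    untyped panel variants are the imputation targets.
    """

    panel: ReferencePanel
    z: np.ndarray
    typed_mask: np.ndarray
    flips: list[str]
    n_ignored: int = 0  # records at positions absent from the panel

    @property
    def typed_indices(self) -> np.ndarray:
        return np.flatnonzero(self.typed_mask)

    @property
    def untyped_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.typed_mask)

    def flip_counts(self) -> Counter:
        return Counter(f for f in self.flips if f is not None)


def harmonize(
    records: Sequence[SumStatRecord],
    panel: ReferencePanel,
    keep_ambiguous: bool = False,
) -> HarmonizedSet:
    """Match records to panel variants by (chrom, pos) and reconcile alleles.

    Matching rules for a record (a1=effect, a2=other) against a panel
    variant (ref, alt):

    * (a1, a2) == (alt, ref): keep Z as is;
    * (a1, a2) == (ref, alt): negate Z (allele swap);
    * reverse-complement matches of the above: strand flip, then same rule;
    * A/T and C/G records: dropped unless ``keep_ambiguous`` (then treated
      as same-strand);
    * irreconcilable alleles: dropped with a warning, never silently kept.

    Records at positions absent from the panel are ignored (they cannot enter
    the LD matrix); rsIDs are never consulted.
    """
    index: dict[tuple[str, int], list[int]] = {}
    for i, (c, p) in enumerate(zip(panel.chrom, panel.pos.tolist())):
        index.setdefault((c, p), []).append(i)

    n = panel.n_variant
    z = np.full(n, np.nan)
    typed = np.zeros(n, dtype=bool)
    flips: list[str | None] = [None] * n
    n_ignored = 0

    for rec in records:
        cands = index.get((rec.chrom, rec.pos))
        if not cands:
            n_ignored += 1
            continue
        if rec.z is None:
            continue
        matched = False
        for i in cands:
            ref, alt = panel.ref[i], panel.alt[i]
            ambiguous = is_strand_ambiguous(rec.a1, rec.a2)
            if ambiguous and not keep_ambiguous:
                if {rec.a1, rec.a2} == {ref, alt}:
                    flips[i] = DROP_AMBIGUOUS
                    matched = True
                    break
                continue
            flip = _reconcile(rec.a1, rec.a2, ref, alt, allow_strand=not ambiguous)
            if flip is None:
                continue
            if typed[i]:
                log.warning(
                    "multiple records map to panel variant %s:%d; keeping first",
                    rec.chrom, rec.pos,
                )
                matched = True
                break
            sign = -1.0 if flip in (FLIP_SWAP, FLIP_STRAND_SWAP) else 1.0
            z[i] = sign * rec.z
            typed[i] = True
            flips[i] = flip
            matched = True
            break
        if not matched:
            i = cands[0]
            flips[i] = DROP_MISMATCH
            log.warning(
                "alleles %s/%s at %s:%d irreconcilable with panel %s/%s; dropped",
                rec.a1, rec.a2, rec.chrom, rec.pos, panel.ref[i], panel.alt[i],
            )

    hset = HarmonizedSet(panel=panel, z=z, typed_mask=typed, flips=flips,
                         n_ignored=n_ignored)
    counts = hset.flip_counts()
    log.info(
        "harmonized %d/%d panel variants typed (%s); %d record(s) off-panel",
        int(typed.sum()), n,
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "none",
        n_ignored,
    )
    return hset


def _reconcile(a1: str, a2: str, ref: str, alt: str, allow_strand: bool) -> str | None:
    if (a1, a2) == (alt, ref):
        return FLIP_NONE
    if (a1, a2) == (ref, alt):
        return FLIP_SWAP
    if allow_strand:
        ra1, ra2 = _revcomp(a1), _revcomp(a2)
        if (ra1, ra2) == (alt, ref):
            return FLIP_STRAND
        if (ra1, ra2) == (ref, alt):
            return FLIP_STRAND_SWAP
    return None
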