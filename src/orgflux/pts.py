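"""Rule-based peroxisomal targeting-signal (PTS) classification.

Two canonical plant signals are scanned for:

* PTS1 — one of nine accepted C-terminal tripeptides
  (SRL, SRM, SRI, ARL, ARM, PRL, SKL, SKM, AKL);
* PTS2 — the nonapeptide R-[LI]-X5-H-L within the N-terminal region
  (residues 1-30).

A PTS call is merged with an external compartment prediction
(TargetP/PredAlgo-style): a PTS on top of a positive external call marks
the protein dual peroxisomal; a PTS alone assigns the peroxisome.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .trees import LocalizationCall, OrgfluxError

logger = logging.getLogger("orgflux")

#: Accepted C-terminal PTS1 tripeptides.
PTS1_TRIPEPTIDES = frozenset(
    ["SRL", "SRM", "SRI", "ARL", "ARM", "PRL", "SKL", "SKM", "AKL"]
)

#: N-terminal window (residues 1..PTS2_WINDOW) that must contain the PTS2 motif.
PTS2_WINDOW = 30
PTS2_LENGTH = 9

_AA = "ACDEFGHIKLMNPQRSTVWYX"
_VALID = re.compile(rf"^[{_AA}]*$")


class SequenceError(OrgfluxError):
    """Non-amino-acid characters in a protein sequence."""


@dataclass(frozen=True)
class PtsResult:
    gene_id: str
    pts1: bool
    pts2: bool
    matched_motif: str | None = None
    motif_start: int | None = None  # 1-based residue index of the PTS2 nonapeptide

    @property
    def has_pts(self) -> bool:
        return self.pts1 or self.pts2


def _clean(sequence: str) -> str:
    seq = sequence.strip().upper().rstrip("*")
    if not _VALID.match(seq):
        bad = sorted({c for c in seq if c not in _AA})
        raise SequenceError(f"non-amino-acid characters in sequence: {bad}")
    return seq


def classify_pts1(sequence: str) -> tuple[bool, str | None]:
    """True iff the final three residues form an accepted PTS1 tripeptide.

    Trailing ``*`` stop symbols and whitespace are stripped first.
    Sequences shorter than three residues are negative.  Ambiguity code
    ``X`` never satisfies a motif position.
    """
    seq = _clean(sequence)
    if len(seq) < 3:
        logger.debug("sequence shorter than 3 residues; PTS1 negative")
        return False, None
    tail = seq[-3:]
    if tail in PTS1_TRIPEPTIDES:
        return True, tail
    return False, None


def classify_pts2(
    sequence: str,
    window: int = PTS2_WINDOW,
    anchor: str = "whole",
) -> tuple[bool, int | None]:
    """Scan for the PTS2 nonapeptide R-[LI]-X5-H-L near the N terminus.

    ``anchor='whole'`` (default) requires the entire 9-mer inside residues
    ``1..window`` (start <= window-8); ``anchor='start'`` only requires the
    match to begin within the window.  The leftmost match is reported as a
    1-based start index.  ``X`` matches only the five wildcard positions.
    """
    if anchor not in ("whole", "start"):
        raise ValueError("anchor must be 'whole' or 'start'")
    seq = _clean(sequence)
    if len(seq) < PTS2_LENGTH:
        return False, None
    last_start = window - PTS2_LENGTH + 1 if anchor == "whole" else window
    for start in range(0, min(last_start, len(seq) - PTS2_LENGTH + 1)):
        win = seq[start : start + PTS2_LENGTH]
        if win[0] == "R" and win[1] in "LI" and win[7] == "H" and win[8] == "L":
            return True, start + 1
    return False, None


def scan_sequence(gene_id: str, sequence: str, **pts2_kwargs) -> PtsResult:
    p1, motif = classify_pts1(sequence)
    p2, start = classify_pts2(sequence, **pts2_kwargs)
    return PtsResult(gene_id, p1, p2, matched_motif=motif, motif_start=start)


def merge_localization(external: LocalizationCall, pts: PtsResult) -> LocalizationCall:
    """Combine an external compartment prediction with the PTS scan.

    A PTS on a protein with a positive external localization yields a
    dual-peroxisomal label; a PTS alone assigns the peroxisome; without a
    PTS the external call stands.  Idempotent.
    """
    if not pts.has_pts:
        return external
    if external.compartment in ("chloroplast", "mitochondrion", "secretory"):
        return LocalizationCall(external.gene_id, external.compartment, dual_peroxisomal=True)
    return LocalizationCall(external.gene_id, "peroxisome", dual_peroxisomal=False)


def scan_fasta(records, **pts2_kwargs) -> list[PtsResult]:
    """Scan Biopython SeqRecords (or (id, seq) pairs)."""
    out = []
    for rec in records:
        if hasattr(rec, "id"):
            out.append(scan_sequence(rec.id, str(rec.seq), **pts2_kwargs))
        else:
            gid, seq = rec
            out.append(scan_sequence(gid, seq, **pts2_kwargs))
    return out
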