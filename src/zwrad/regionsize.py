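"""Restriction-site density arithmetic for sex-linked region sizes.

Under an i.i.d. base-composition model, an unambiguous recognition
motif occurs at any position with probability

    p = (gc/2)^n_GC * ((1-gc)/2)^n_AT,

so consecutive sites are 1/p bp apart on average, and each site yields
two RAD markers (one per flank).  Counting the completely sex-linked
markers of a population, halving to get restriction sites, and
multiplying by the expected spacing gives a rough physical extent of
the sex-linked region.  SbfI's 8-bp site (CCTGCAGG) is its own reverse
complement, so a single-strand scan suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalogue import ValidationError

SBFI_MOTIF = "CCTGCAGG"


@dataclass(frozen=True)
class SpacingEstimate:
    motif: str
    gc: float
    p_site: float
    spacing_bp: float
    spacing_rounded_kb: float  # nearest multiple of 100 kb, at least 100


def site_probability(motif: str, gc: float) -> float:
    """Per-position probability of an unambiguous motif at GC content ``gc``."""
    if not motif:
        raise ValidationError("motif must be non-empty")
    bad = set(motif.upper()) - set("ACGT")
    if bad:
        raise ValidationError(
            f"ambiguous or invalid bases {sorted(bad)} are not supported"
        )
    if not 0 < gc < 1:
        raise ValidationError("gc must lie strictly between 0 and 1")
    n_gc = sum(1 for b in motif.upper() if b in "GC")
    n_at = len(motif) - n_gc
    return (gc / 2.0) ** n_gc * ((1.0 - gc) / 2.0) ** n_at


def expected_spacing(p_site: float, motif: str = SBFI_MOTIF, gc: float = 0.47) -> SpacingEstimate:
    """Expected distance between sites, exact and rounded to 100 kb."""
    if p_site <= 0:
        raise ValidationError("p_site must be > 0")
    spacing_bp = 1.0 / p_site
    rounded = max(100.0, round(spacing_bp / 1000.0 / 100.0) * 100.0)
    return SpacingEstimate(motif, gc, p_site, spacing_bp, rounded)


def sbfi_spacing(gc: float = 0.47) -> SpacingEstimate:
    return expected_spacing(site_probability(SBFI_MOTIF, gc), SBFI_MOTIF, gc)


def region_extent(
    spacing: SpacingEstimate,
    n_markers: int | None = None,
    n_sites: int | None = None,
) -> float:
    """Extent (kb) implied by a count of sex-linked markers or sites.

    Two markers flank each restriction site, so ``n_sites =
    round(n_markers / 2)`` with ties to even; the extent is sites times
    the *rounded* spacing (the exact spacing stays available on the
    estimate for anyone who prefers it unrounded).
    """
    if (n_markers is None) == (n_sites is None):
        raise ValidationError("give exactly one of n_markers or n_sites")
    if n_sites is None:
        if n_markers < 0:
            raise ValidationError("n_markers must be >= 0")
        n_sites = round(n_markers / 2.0)
    if n_sites < 0:
        raise ValidationError("n_sites must be >= 0")
    return n_sites * spacing.spacing_rounded_kb
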