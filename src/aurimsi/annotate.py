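"""Adduct-based metabolite annotation within a ppm tolerance.

Matches a calibrated dataset-level peak list against a table of
neutral metabolite formulas over a configurable positive-mode adduct
set (default +H, +Na, +K, +NH4, all z=1), emitting every
(peak, metabolite, adduct) pair whose signed mass error is within the
tolerance (default 20 ppm). All identifications are putative —
formula-level only, no isomer disambiguation, no scoring beyond |ppm|.

Multiply-charged double adducts (e.g. ``+H+NH4`` at z=2) are supported
via :func:`aurimsi.chem.parse_adduct` but excluded from the default
set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import AdductSpec, STANDARD_ADDUCTS, ion_mz, parse_adduct, ppm_error
from .io import MSIDataset, MetaboliteRecord
from .preprocess import Peak

__all__ = ["AnnotationHit", "annotate", "hits_to_frame", "cross_adduct_consistency"]


@dataclass(frozen=True)
class AnnotationHit:
    """One putative identification: a row of the annotation table."""

    peak_mz: float
    metabolite: str
    neutral_formula: str
    adduct: AdductSpec
    theoretical_mz: float
    ppm: float
    tissue_reported: bool = False

    @property
    def ion_formula(self) -> str:
        return f"[{self.neutral_formula}{self.adduct.label}]{self.adduct.charge if self.adduct.charge > 1 else ''}+"


def annotate(
    peaks: Sequence[Peak] | Sequence[float],
    db: Sequence[MetaboliteRecord],
    adducts: Sequence[AdductSpec | str] | None = None,
    tol_ppm: float = 20.0,
    tissue: str | None = None,
) -> list[AnnotationHit]:
    """Annotate a peak list against a metabolite table.

    ``peaks`` may be :class:`Peak` objects or bare m/z values. Every
    (peak, metabolite, adduct) combination within ``tol_ppm`` is
    emitted — a peak can have several candidates and a metabolite can
    appear under several adducts. Hits are sorted by peak m/z, then
    |ppm|, then name, independent of input order. When ``tissue`` is
    given, ``tissue_reported`` flags metabolites whose database record
    lists that tissue.
    """
    if adducts is None:
        adducts = STANDARD_ADDUCTS
    specs = [parse_adduct(a) if isinstance(a, str) else a for a in adducts]
    if not specs:
        raise ValueError("empty adduct set")
    mzs = np.array([p.mz if isinstance(p, Peak) else float(p) for p in peaks])
    hits: list[AnnotationHit] = []
    for rec in db:
        for spec in specs:
            theo = ion_mz(rec.neutral_formula, spec, electron_correction=True)
            errs = (theo - mzs) / theo * 1e6
            for j in np.flatnonzero(np.abs(errs) <= tol_ppm):
                hits.append(
                    AnnotationHit(
                        float(mzs[j]),
                        rec.name,
                        rec.neutral_formula.hill_formula(),
                        spec,
                        theo,
                        float(errs[j]),
                        tissue is not None and tissue.lower() in rec.reported_in_tissue,
                    )
                )
    hits.sort(key=lambda h: (h.peak_mz, abs(h.ppm), h.metabolite, h.adduct.label))
    return hits


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    """Annotation table with the five classic columns + adduct and tissue flag."""
    return pd.DataFrame(
        {
            "name": [h.metabolite for h in hits],
            "ion_formula": [h.ion_formula for h in hits],
            "adduct": [h.adduct.label for h in hits],
            "mz_experimental": [h.peak_mz for h in hits],
            "mz_theoretical": [h.theoretical_mz for h in hits],
            "ppm_error": [h.ppm for h in hits],
            "tissue_reported": [h.tissue_reported for h in hits],
        }
    )


def cross_adduct_consistency(
    hits: Sequence[AnnotationHit],
    dataset: MSIDataset | None = None,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Group hits by neutral formula; score spatial consistency across adducts.

    A metabolite detected under two adducts (say +Na and +K) should
    show the same spatial distribution; the Pearson correlation between
    the two adducts' ion images is a cheap consistency check on the
    identification. Groups with a single adduct get a NaN score.
    Requires ``dataset`` (profile data) to build the images.
    """
    from .imaging import ion_image

    groups: dict[str, list[AnnotationHit]] = {}
    for h in hits:
        groups.setdefault(h.neutral_formula, []).append(h)
    rows = []
    for formula, members in sorted(groups.items()):
        adduct_mz = sorted({(m.adduct.label, m.theoretical_mz) for m in members})
        score = np.nan
        pair = ""
        if len(adduct_mz) >= 2 and dataset is not None:
            best: list[float] = []
            for (la, ma), (lb, mb) in combinations(adduct_mz, 2):
                ia = ion_image(dataset, ma, tolerance).grid.ravel()
                ib = ion_image(dataset, mb, tolerance).grid.ravel()
                ok = np.isfinite(ia) & np.isfinite(ib)
                if ok.sum() > 2 and ia[ok].std() > 0 and ib[ok].std() > 0:
                    r = float(np.corrcoef(ia[ok], ib[ok])[0, 1])
                    if not best or r > best[0]:
                        best = [r]
                        pair = f"{la}/{lb}"
            if best:
                score = best[0]
        rows.append(
            {
                "neutral_formula": formula,
                "names": ";".join(sorted({m.metabolite for m in members})),
                "n_adducts": len(adduct_mz),
                "adducts": ";".join(l for l, _ in adduct_mz),
                "spatial_correlation": score,
                "scored_pair": pair,
            }
        )
    return pd.DataFrame(rows)
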