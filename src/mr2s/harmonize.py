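"""Allele harmonization, OR/CI conversion, LD pruning and proxy lookup.

Two-sample MR requires the exposure effect (gamma) and the outcome effect
(Gamma) of every instrument to refer to the *same* effect allele.  This
module aligns record pairs, converts odds-ratio/CI outcome effects to
log-odds with a reconstructed SE, substitutes high-LD proxy variants when
the index SNP was not genotyped on the outcome platform, and greedily
prunes instruments so that no retained pair exceeds an r-squared ceiling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from mr2s.errors import DomainError, HarmonizationError
from mr2s.summary_io import Fixture, SummaryRecord

log = logging.getLogger("mr2s.harmonize")

#: Two-sided 97.5% normal quantile, carried to more digits than the printed
#: CIs so reconstructed SEs are reproducible.
Z975 = 1.959964

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Flag names carried on HarmonizedInstrument.flags.
FLAG_AF_BAND = "af_band_0.4_0.6"
FLAG_HEIGHT_LD = "height_ld"
FLAG_PALINDROMIC = "palindromic_unresolved"


@dataclass
class HarmonizedInstrument:
    """An exposure/outcome SNP pair aligned onto one shared effect allele.

    ``gamma`` is the per-allele exposure effect (SD units for a continuous
    exposure), ``Gamma`` the outcome effect (log-odds for a binary
    outcome); both refer to the same ``effect_allele``.  ``proxy_id`` is
    None when the outcome association was measured on the index SNP itself.
    """

    snp_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    effect_allele: Optional[str] = None
    eaf: Optional[float] = None
    outcome_source: str = ""
    proxy_id: Optional[str] = None
    proxy_r2: float = 1.0
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.se_gamma <= 0 or self.se_Gamma <= 0:
            raise DomainError(f"{self.snp_id}: standard errors must be positive")
        # selection requires r2 > 0.8 but published tables round to 2 dp,
        # so a genuine 0.80x proxy can print as 0.80: closed bound here
        if not 0.8 <= self.proxy_r2 <= 1.0:
            raise DomainError(f"{self.snp_id}: proxy r2 {self.proxy_r2} outside [0.8, 1.0]")

    @property
    def is_proxy(self) -> bool:
        return self.proxy_id is not None


class LDTable:
    """Symmetric sparse pairwise r-squared lookup keyed by SNP id pairs.

    An absent pair means "unknown", which pruning treats as independence
    (general inputs, unlike a fully measured panel, rarely cover all pairs).
    """

    def __init__(self, pairs: Optional[Iterable[tuple[str, str, float]]] = None):
        self._pairs: dict[frozenset, float] = {}
        for a, b, r2 in pairs or []:
            self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise DomainError(f"r2 {r2} for ({a}, {b}) outside [0, 1]")
        self._pairs[frozenset((a, b))] = r2

    def get(self, a: str, b: str) -> Optional[float]:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)))

    def snp_ids(self) -> set:
        out: set = set()
        for key in self._pairs:
            out |= set(key)
        return out

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_tsv(cls, path) -> "LDTable":
        """Read a 3-column (snp_a, snp_b, r2) TSV with a header row."""
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                a, b, r2 = line.rstrip("\n").split("\t")
                table.set(a, b, float(r2))
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("snp_a\tsnp_b\tr2\n")
            for key in sorted(self._pairs, key=sorted):
                a, b = sorted(key) if len(key) == 2 else (list(key)[0],) * 2
                fh.write(f"{a}\t{b}\t{self._pairs[key]!r}\n")


def or_to_log(or_: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Convert an odds ratio with 95% CI to (log-odds, SE).

    SE is reconstructed from the CI log-width: ``(ln hi - ln lo) / (2 z)``
    with z = 1.959964.  A zero-width CI has no information about the SE and
    is rejected.
    """
    if or_ <= 0 or ci_low <= 0 or ci_high <= 0:
        raise DomainError(f"odds ratio and CI must be positive, got ({or_}, {ci_low}, {ci_high})")
    if not ci_low <= or_ <= ci_high:
        raise DomainError(f"CI ({ci_low}, {ci_high}) does not bracket OR {or_}")
    if ci_low == ci_high:
        raise DomainError("degenerate zero-width CI: SE cannot be reconstructed")
    beta = math.log(or_)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z975)
    return beta, se


def log_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Inverse of :func:`or_to_log`: (OR, 95% CI low, 95% CI high)."""
    return math.exp(beta), math.exp(beta - Z975 * se), math.exp(beta + Z975 * se)


def se_from_pvalue(beta: float, pvalue: float) -> float:
    """Reconstruct a Wald SE from an effect size and its two-sided p-value."""
    if beta == 0:
        raise DomainError("cannot reconstruct SE for a zero effect")
    z = stats.norm.isf(pvalue / 2.0)
    if not np.isfinite(z) or z <= 0:
        raise DomainError(f"p-value {pvalue} gives no usable z-score")
    return abs(beta) / z


def _outcome_effect(rec: SummaryRecord) -> tuple[float, float]:
    """Outcome effect as (log-odds beta, SE), whichever encoding is present."""
    if rec.beta is not None and rec.se is not None:
        return rec.beta, rec.se
    if rec.or_ is not None and rec.ci_low is not None and rec.ci_high is not None:
        return or_to_log(rec.or_, rec.ci_low, rec.ci_high)
    raise HarmonizationError(f"{rec.snp_id}: outcome record has neither beta/se nor OR/CI")


def _exposure_se(rec: SummaryRecord) -> float:
    if rec.se is not None:
        return rec.se
    if rec.pvalue is not None and rec.beta not in (None, 0.0):
        return se_from_pvalue(rec.beta, rec.pvalue)
    raise HarmonizationError(f"{rec.snp_id}: exposure SE not present and not reconstructible")


def is_palindromic(a1: Optional[str], a2: Optional[str]) -> bool:
    if a1 is None or a2 is None:
        return False
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_pair(
    exposure: SummaryRecord,
    outcome: SummaryRecord,
    mode: str = "alleles",
    proxy_id: Optional[str] = None,
    proxy_r2: float = 1.0,
) -> HarmonizedInstrument:
    """Align one exposure/outcome record pair onto the exposure's effect allele.

    ``mode="alleles"`` matches the outcome's alleles to the exposure's,
    negating the outcome effect (and complementing its AF) when it is
    reported on the other allele, and trying the strand complement before
    giving up.  Palindromic SNPs (A/T, C/G) with AF in [0.4, 0.6] cannot be
    resolved and are flagged, not dropped.

    ``mode="pre_oriented"`` asserts both records already refer to the
    exposure-increasing allele (the situation of published instrument
    tables that print only that allele) and copies effects through.
    """
    if mode not in ("alleles", "pre_oriented"):
        raise DomainError(f"unknown harmonization mode {mode!r}")
    if proxy_id is None and exposure.snp_id != outcome.snp_id:
        raise HarmonizationError(
            f"snp_id mismatch ({exposure.snp_id} vs {outcome.snp_id}) without a designated proxy"
        )

    gamma = exposure.beta
    if gamma is None:
        raise HarmonizationError(f"{exposure.snp_id}: exposure record has no beta")
    se_gamma = _exposure_se(exposure)
    Gamma, se_Gamma = _outcome_effect(outcome)
    eaf = exposure.eaf if exposure.eaf is not None else outcome.eaf
    flags: set = set()

    if mode == "alleles":
        ea, oa = exposure.effect_allele, exposure.other_allele
        out_ea, out_oa = outcome.effect_allele, outcome.other_allele
        if not all((ea, oa, out_ea, out_oa)):
            raise HarmonizationError(
                f"{exposure.snp_id}: 'alleles' mode requires effect and other alleles on both records"
            )
        ea, oa, out_ea, out_oa = (x.upper() for x in (ea, oa, out_ea, out_oa))
        comp = lambda x: _COMPLEMENT[x]
        if (out_ea, out_oa) == (ea, oa):
            pass
        elif (out_ea, out_oa) == (oa, ea):
            Gamma = -Gamma
            if outcome.eaf is not None and exposure.eaf is None:
                eaf = 1.0 - outcome.eaf
        elif (comp(out_ea), comp(out_oa)) == (ea, oa):
            pass  # same orientation on the other strand
        elif (comp(out_ea), comp(out_oa)) == (oa, ea):
            Gamma = -Gamma
            if outcome.eaf is not None and exposure.eaf is None:
                eaf = 1.0 - outcome.eaf
        else:
            raise HarmonizationError(
                f"{exposure.snp_id}: irreconcilable alleles "
                f"exposure {ea}/{oa} vs outcome {out_ea}/{out_oa}"
            )
        if is_palindromic(ea, oa) and eaf is not None and 0.4 <= eaf <= 0.6:
            flags.add(FLAG_PALINDROMIC)

    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        gamma=gamma,
        se_gamma=se_gamma,
        Gamma=Gamma,
        se_Gamma=se_Gamma,
        effect_allele=exposure.effect_allele,
        eaf=eaf,
        outcome_source=outcome.source,
        proxy_id=proxy_id,
        proxy_r2=proxy_r2,
        flags=flags,
    )


def attach_af_band_flag(
    inst: HarmonizedInstrument, low: float = 0.4, high: float = 0.6
) -> HarmonizedInstrument:
    """Flag proxied instruments whose effect-allele frequency falls in the
    closed band [low, high].

    Near-0.5 frequencies make allele matching across studies fragile, so
    proxies in this band are the ones a frequency-based sensitivity
    analysis removes.  Directly genotyped instruments are never flagged.
    """
    if inst.eaf is None:
        log.warning("%s: no EAF, allele-frequency band flag not evaluated", inst.snp_id)
        return inst
    if inst.is_proxy and low <= inst.eaf <= high:
        return replace(inst, flags=inst.flags | {FLAG_AF_BAND})
    return inst


def r2_from_dosages(x: Sequence[float], y: Sequence[float]) -> float:
    """LD between two variants as the squared Pearson correlation of their
    allele-dosage vectors (values in [0, 2])."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DomainError("dosage vectors must be equal-length 1-D with n >= 3")
    if np.any((x < 0) | (x > 2)) or np.any((y < 0) | (y > 2)):
        raise DomainError("dosages must lie in [0, 2]")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise DomainError("zero-variance dosage vector")
    r2 = float((xc @ yc) ** 2 / (vx * vy))
    return min(r2, 1.0)


def ld_prune(
    snps: Sequence[tuple[str, float]],
    ld: LDTable,
    r2_max: float = 0.05,
) -> list[str]:
    """Greedy LD pruning of (snp_id, exposure p-value) pairs.

    SNPs are visited in ascending p-value order (ties broken by snp_id) and
    accepted only if their r-squared with every already-accepted SNP is at
    most ``r2_max`` or unknown; the strongest-associated member of any
    correlated group therefore survives.  Output preserves acceptance
    order, which makes the result independent of input row order.
    """
    retained: list[str] = []
    for snp_id, _p in sorted(snps, key=lambda t: (t[1], t[0])):
        ok = True
        for kept in retained:
            r2 = ld.get(snp_id, kept)
            if r2 is not None and r2 > r2_max:
                ok = False
                break
        if ok:
            retained.append(snp_id)
    return retained


def find_proxy(
    target: str,
    available: Sequence[tuple[str, Iterable[str]]],
    ld: LDTable,
    r2_min: float = 0.8,
) -> Optional[tuple[str, float, str]]:
    """Find the outcome variant standing in for ``target``.

    ``available`` is an ordered list of ``(source_label, snp_ids)`` in
    priority order.  If the target itself is genotyped in a source, it is
    its own proxy with r2 = 1.  Otherwise each source is searched in turn
    for the candidate with the largest known r-squared strictly above
    ``r2_min`` (ties broken lexicographically).  Returns None if no source
    qualifies.
    """
    for source, snp_ids in available:
        if target in set(snp_ids):
            return target, 1.0, source
    for source, snp_ids in available:
        best: Optional[tuple[float, str]] = None
        for cand in snp_ids:
            r2 = ld.get(target, cand)
            if r2 is None or not r2 > r2_min:
                continue
            # max r2; on exact ties keep the lexicographically smaller id
            if best is None or r2 > best[0] or (r2 == best[0] and cand < best[1]):
                best = (r2, cand)
        if best is not None:
            return best[1], best[0], source
    return None


def harmonize_fixture(fixture: Fixture) -> list[HarmonizedInstrument]:
    """Harmonize the packaged instrument table into 70 instruments.

    The table prints only the exposure-increasing allele, so harmonization
    runs in ``pre_oriented`` mode; allele-frequency band flags are attached
    so sensitivity filters can act on them.
    """
    instruments = []
    for exp, out in zip(fixture.exposure_records, fixture.outcome_records):
        proxy_id, r2, _src = fixture.proxy_map[exp.snp_id]
        inst = harmonize_pair(
            exp,
            out,
            mode="pre_oriented",
            proxy_id=None if proxy_id == exp.snp_id else proxy_id,
            proxy_r2=r2,
        )
        instruments.append(attach_af_band_flag(inst))
    log.info(
        "harmonized %d instruments (%d proxied)",
        len(instruments),
        sum(i.is_proxy for i in instruments),
    )
    return instruments
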