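"""Sensitivity suites and the bidirectional analysis.

Each sensitivity analysis is a named :class:`AnalysisSpec`: an ordered list
of declarative instrument filters plus the estimators to rerun on the
surviving set.  The canonical suite mirrors the proxy-robustness checks of
the packaged study: all instruments, proxies with near-0.5 allele
frequencies removed, and all proxies removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from mr2s.errors import ConfigError, DomainError, MRError
from mr2s.harmonize import FLAG_AF_BAND, HarmonizedInstrument, LDTable
from mr2s.mr_core import (
    DEFAULT_N_BOOT,
    DEFAULT_SEED,
    MRResult,
    egger,
    ivw_fixed,
    weighted_median,
)

log = logging.getLogger("mr2s.sensitivity")

FILTER_NAMES = ("drop_proxies", "drop_af_band_proxies", "drop_height_ld")
ESTIMATOR_NAMES = ("IVW_fixed", "Egger", "WeightedMedian")
HEIGHT_LD_R2_MAX = 0.05


@dataclass
class AnalysisSpec:
    """One named sensitivity analysis: filters to apply, estimators to run.

    ``filters`` entries are the names in :data:`FILTER_NAMES` or
    ``"restrict_source:<label>"``.
    """

    name: str
    filters: list = field(default_factory=list)
    estimators: tuple = ESTIMATOR_NAMES

    def __post_init__(self) -> None:
        for f in self.filters:
            if f not in FILTER_NAMES and not f.startswith("restrict_source:"):
                raise ConfigError(f"{self.name}: unknown filter {f!r}")
        for e in self.estimators:
            if e not in ESTIMATOR_NAMES:
                raise ConfigError(f"{self.name}: unknown estimator {e!r}")


def default_specs() -> list[AnalysisSpec]:
    """The canonical three-analysis suite (primary + two proxy checks)."""
    return [
        AnalysisSpec("all_snps", []),
        AnalysisSpec("af_band_proxies_excluded", ["drop_af_band_proxies"]),
        AnalysisSpec("all_proxies_excluded", ["drop_proxies"]),
    ]


def apply_filters(
    instruments: Sequence[HarmonizedInstrument],
    spec: AnalysisSpec,
    height_loci_ld: Optional[LDTable] = None,
    height_loci: Optional[Sequence[str]] = None,
) -> list[HarmonizedInstrument]:
    """Apply a spec's filters in listed order and return the survivors.

    * ``drop_proxies`` keeps only directly genotyped instruments;
    * ``drop_af_band_proxies`` removes instruments flagged as proxies with
      effect-allele frequency in [0.4, 0.6];
    * ``drop_height_ld`` removes instruments with r2 > 0.05 to any height
      locus (requires an LD table; the locus list defaults to every id in
      the table that is not itself an instrument);
    * ``restrict_source:<label>`` keeps instruments whose outcome source
      matches the label.
    """
    kept = list(instruments)
    for f in spec.filters:
        if f == "drop_proxies":
            kept = [i for i in kept if not i.is_proxy]
        elif f == "drop_af_band_proxies":
            kept = [i for i in kept if FLAG_AF_BAND not in i.flags]
        elif f == "drop_height_ld":
            if height_loci_ld is None:
                raise ConfigError(f"{spec.name}: drop_height_ld requires an LD table")
            inst_ids = {i.snp_id for i in kept}
            loci = list(height_loci) if height_loci is not None else sorted(
                height_loci_ld.snp_ids() - inst_ids
            )
            kept = [i for i in kept if not _in_ld_with_any(i.snp_id, loci, height_loci_ld)]
        elif f.startswith("restrict_source:"):
            label = f.split(":", 1)[1]
            kept = [i for i in kept if i.outcome_source == label]
        log.info("%s: after %s, %d instruments remain", spec.name, f, len(kept))
    return kept


def _in_ld_with_any(snp_id: str, loci: Sequence[str], ld: LDTable) -> bool:
    for locus in loci:
        if locus == snp_id:
            return True
        r2 = ld.get(snp_id, locus)
        if r2 is not None and r2 > HEIGHT_LD_R2_MAX:
            return True
    return False


@dataclass
class SuiteRow:
    """One (analysis, estimator) cell of a suite run."""

    spec_name: str
    method: str
    result: Optional[MRResult]
    n_snps: int
    n_proxies: int
    error: Optional[str] = None


def _run_estimators(
    instruments: Sequence[HarmonizedInstrument],
    estimators: Sequence[str],
    n_boot: int,
    seed: int,
) -> dict[str, MRResult]:
    out: dict[str, MRResult] = {}
    for est in estimators:
        if est == "IVW_fixed":
            out["IVW_fixed"] = ivw_fixed(instruments)
        elif est == "Egger":
            intercept, slope = egger(instruments)
            out["Egger_intercept"] = intercept
            out["Egger_slope"] = slope
        elif est == "WeightedMedian":
            out["WeightedMedian"] = weighted_median(instruments, n_boot=n_boot, seed=seed)
    return out


def run_suite(
    instruments: Sequence[HarmonizedInstrument],
    specs: Sequence[AnalysisSpec],
    height_loci_ld: Optional[LDTable] = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
) -> list[SuiteRow]:
    """Run every spec x estimator combination, one row per result.

    A spec whose filters leave fewer than 3 instruments is marked failed
    (one row, ``error`` set) and the run continues; estimator errors are
    captured the same way.
    """
    if not specs:
        raise ConfigError("suite needs at least one analysis spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate analysis names in suite: {names}")
    rows: list[SuiteRow] = []
    for spec in specs:
        kept = apply_filters(instruments, spec, height_loci_ld=height_loci_ld)
        n, n_proxy = len(kept), sum(i.is_proxy for i in kept)
        log.info("analysis %s: %d instruments (%d proxies)", spec.name, n, n_proxy)
        if n < 3:
            rows.append(
                SuiteRow(spec.name, "-", None, n, n_proxy, error=f"only {n} instruments after filtering")
            )
            continue
        try:
            results = _run_estimators(kept, spec.estimators, n_boot, seed)
        except MRError as exc:
            rows.append(SuiteRow(spec.name, "-", None, n, n_proxy, error=str(exc)))
            continue
        for method, res in results.items():
            rows.append(SuiteRow(spec.name, method, res, n, n_proxy))
    return rows


def swap_roles(inst: HarmonizedInstrument) -> HarmonizedInstrument:
    """Exchange the exposure and outcome sides of an instrument (an
    involution: applying it twice restores the original)."""
    return HarmonizedInstrument(
        snp_id=inst.snp_id,
        gamma=inst.Gamma,
        se_gamma=inst.se_Gamma,
        Gamma=inst.gamma,
        se_Gamma=inst.se_gamma,
        effect_allele=inst.effect_allele,
        eaf=inst.eaf,
        outcome_source=inst.outcome_source,
        proxy_id=inst.proxy_id,
        proxy_r2=inst.proxy_r2,
        flags=set(inst.flags),
    )


def bidirectional(
    reversed_instruments: Sequence[HarmonizedInstrument],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
) -> dict[str, MRResult]:
    """Reverse-direction analysis: outcome-trait instruments as exposure.

    The caller supplies instruments already harmonized with the roles
    swapped (e.g. disease log-odds as gamma, trait SD units as Gamma); the
    identical estimator stack runs and results are tagged with the
    ``reverse:`` prefix.  Effects are then in SD of the original exposure
    per log-odds of the original outcome.
    """
    if len(reversed_instruments) < 3:
        raise DomainError("bidirectional analysis needs at least 3 instruments")
    results = _run_estimators(reversed_instruments, ESTIMATOR_NAMES, n_boot, seed)
    out = {}
    for method, res in results.items():
        res.method = f"reverse:{method}"
        out[method] = res
    return out
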