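"""Reading, harmonizing, standardizing, and selecting GWAS summary statistics.

The raw inputs to multivariable MR are per-variant association estimates from
p exposure GWAS and one outcome GWAS. Before any estimation the studies must
be restricted to shared variants, aligned to a single effect-allele
orientation, and placed on a common (standardized) scale. This module owns
that plumbing and the instrument-selection step (p-value threshold plus
distance pruning of a pre-pruned or to-be-pruned variant set).

Coordinates are 1-based inclusive, following GWAS summary-statistic
convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ColumnMappingError,
    EmptyInputError,
    EmptyIntersectionError,
    EmptySelectionError,
    StandardizationStateError,
)

logger = logging.getLogger(__name__)

#: column roles accepted by :func:`read_summary_table`
ROLES = (
    "id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "effect",
    "standard_error",
    "sample_size",
    "p_value",
    "allele_frequency",
)
MANDATORY_ROLES = ("id", "effect_allele", "other_allele", "effect", "standard_error")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantRecord:
    """One GWAS association record for a single variant."""

    variant_id: str
    effect_allele: str
    other_allele: str
    effect: float
    standard_error: float
    chromosome: str | None = None
    position: int | None = None
    sample_size: int | None = None
    p_value: float | None = None
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.standard_error <= 0:
            raise ValueError(f"standard_error must be positive ({self.variant_id})")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"effect_allele equals other_allele ({self.variant_id})")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) allele pairs."""
        return _COMPLEMENT.get(self.effect_allele.upper()) == self.other_allele.upper()


@dataclass
class HarmonizedPanel:
    """Aligned per-variant exposure and outcome estimates for MR.

    Rows index m variants shared by all p+1 studies, all oriented to one
    reference effect allele. ``outcome_estimates`` is an (m,) vector for the
    usual single-outcome case and an (m, q) matrix when q outcomes share the
    instrument set (multi-outcome fitting).
    """

    variant_ids: list[str]
    exposure_estimates: np.ndarray  # (m, p)
    outcome_estimates: np.ndarray  # (m,) or (m, q)
    exposure_ses: np.ndarray  # (m, p)
    outcome_ses: np.ndarray  # (m,) or (m, q)
    exposure_names: list[str]
    standardization: str = "none"  # by_se_sqrt_n | by_se_only | none
    chromosomes: np.ndarray | None = None  # (m,) object/str
    positions: np.ndarray | None = None  # (m,) int
    exposure_n: np.ndarray | None = None  # (m, p)
    outcome_n: np.ndarray | None = None  # (m,) or (m, q)
    exposure_pvalues: np.ndarray | None = None  # (m, p)
    outcome_pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.exposure_estimates = np.atleast_2d(np.asarray(self.exposure_estimates, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        self.outcome_estimates = np.asarray(self.outcome_estimates, float)
        self.outcome_ses = np.asarray(self.outcome_ses, float)
        m = len(self.variant_ids)
        for arr in (self.exposure_estimates, self.outcome_estimates,
                    self.exposure_ses, self.outcome_ses):
            if arr.shape[0] != m:
                raise ValueError("all panel arrays must share the variant count")

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    @property
    def p(self) -> int:
        return self.exposure_estimates.shape[1]

    @property
    def n_outcomes(self) -> int:
        return 1 if self.outcome_estimates.ndim == 1 else self.outcome_estimates.shape[1]

    def subset(self, index: np.ndarray | Sequence[int]) -> "HarmonizedPanel":
        """Return a panel restricted to the given row indices (order kept)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)

        def take(a):
            return None if a is None else np.asarray(a)[idx]

        return HarmonizedPanel(
            variant_ids=[self.variant_ids[i] for i in idx],
            exposure_estimates=self.exposure_estimates[idx],
            outcome_estimates=self.outcome_estimates[idx],
            exposure_ses=self.exposure_ses[idx],
            outcome_ses=self.outcome_ses[idx],
            exposure_names=list(self.exposure_names),
            standardization=self.standardization,
            chromosomes=take(self.chromosomes),
            positions=take(self.positions),
            exposure_n=take(self.exposure_n),
            outcome_n=take(self.outcome_n),
            exposure_pvalues=take(self.exposure_pvalues),
            outcome_pvalues=take(self.outcome_pvalues),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Flat table: variant_id, chr, pos, then per-study effect/SE pairs."""
        d: dict[str, object] = {"variant_id": self.variant_ids}
        if self.chromosomes is not None:
            d["chr"] = self.chromosomes
        if self.positions is not None:
            d["pos"] = self.positions
        for k, name in enumerate(self.exposure_names):
            d[f"{name}_effect"] = self.exposure_estimates[:, k]
            d[f"{name}_se"] = self.exposure_ses[:, k]
        out = np.atleast_2d(self.outcome_estimates.T).T
        out_se = np.atleast_2d(self.outcome_ses.T).T
        for q in range(out.shape[1]):
            tag = "outcome" if out.shape[1] == 1 else f"outcome{q + 1}"
            d[f"{tag}_effect"] = out[:, q]
            d[f"{tag}_se"] = out_se[:, q]
        return pd.DataFrame(d)

    def write(self, path) -> None:
        """Write the panel as a tab-delimited table with a header row."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def read_panel(path) -> HarmonizedPanel:
    """Read a harmonized panel written by :meth:`HarmonizedPanel.write`.

    Expects columns ``variant_id`` (optionally ``chr``/``pos``), per-exposure
    ``<name>_effect``/``<name>_se`` pairs, and ``outcome_effect``/
    ``outcome_se`` (or ``outcome1_...`` etc. for multiple outcomes). Lines
    starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "variant_id" not in df.columns:
        raise ColumnMappingError(f"{path} has no variant_id column")
    eff = [c for c in df.columns if c.endswith("_effect")]
    exp_names = [c[:-7] for c in eff if not c.startswith("outcome")]
    out_names = [c[:-7] for c in eff if c.startswith("outcome")]
    if not exp_names or not out_names:
        raise ColumnMappingError(f"{path} lacks exposure or outcome effect columns")
    for name in exp_names + out_names:
        if f"{name}_se" not in df.columns:
            raise ColumnMappingError(f"{path} has {name}_effect without {name}_se")
    out_est = df[[f"{n}_effect" for n in out_names]].to_numpy(float)
    out_se = df[[f"{n}_se" for n in out_names]].to_numpy(float)
    if len(out_names) == 1:
        out_est, out_se = out_est[:, 0], out_se[:, 0]
    return HarmonizedPanel(
        variant_ids=[str(v) for v in df["variant_id"]],
        exposure_estimates=df[[f"{n}_effect" for n in exp_names]].to_numpy(float),
        outcome_estimates=out_est,
        exposure_ses=df[[f"{n}_se" for n in exp_names]].to_numpy(float),
        outcome_ses=out_se,
        exposure_names=exp_names,
        chromosomes=df["chr"].astype(str).to_numpy() if "chr" in df.columns else None,
        positions=df["pos"].astype(int).to_numpy() if "pos" in df.columns else None,
    )


def read_summary_table(
    path,
    column_map: Mapping[str, str],
    sep: str | None = None,
) -> list[VariantRecord]:
    """Read one GWAS summary-statistics table into variant records.

    Parameters
    ----------
    path
        Delimited text file with a header row (tab or comma; sniffed when
        ``sep`` is None).
    column_map
        Mapping from role (see :data:`ROLES`) to the column name in the file.
        Must cover at least ``id``, ``effect_allele``, ``other_allele``,
        ``effect`` and ``standard_error``.

    Rows with non-positive standard errors or unparseable numeric fields are
    dropped, with the drop count logged.
    """
    for role in MANDATORY_ROLES:
        if role not in column_map:
            raise ColumnMappingError(f"column_map is missing mandatory role {role!r}")
    unknown = set(column_map) - set(ROLES)
    if unknown:
        raise ColumnMappingError(f"unknown column roles: {sorted(unknown)}")

    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing_cols = [c for c in column_map.values() if c not in df.columns]
    if missing_cols:
        roles = [r for r, c in column_map.items() if c in missing_cols]
        raise ColumnMappingError(
            f"columns {missing_cols} (roles {roles}) not found in {path}"
        )
    if df.empty:
        raise EmptyInputError(f"{path} contains a header but no data rows")

    sub = df[[column_map[r] for r in column_map]].copy()
    sub.columns = list(column_map)
    numeric_roles = [r for r in ("effect", "standard_error", "p_value",
                                 "allele_frequency", "sample_size", "position")
                     if r in sub.columns]
    for r in numeric_roles:
        sub[r] = pd.to_numeric(sub[r], errors="coerce")

    n0 = len(sub)
    keep = sub["effect"].notna() & sub["standard_error"].notna() & (sub["standard_error"] > 0)
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.info("read_summary_table: dropped %d of %d rows (bad SE or numerics)",
                    dropped, n0)
    sub = sub[keep]
    if sub.empty:
        raise EmptyInputError(f"{path}: no rows survived parsing")

    def opt(row, role, cast):
        if role not in sub.columns:
            return None
        v = row[role]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return cast(v)

    records = []
    for row in sub.itertuples(index=False):
        row = row._asdict()
        records.append(VariantRecord(
            variant_id=str(row["id"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            effect=float(row["effect"]),
            standard_error=float(row["standard_error"]),
            chromosome=opt(row, "chromosome", str),
            position=opt(row, "position", lambda v: int(v)),
            sample_size=opt(row, "sample_size", lambda v: int(v)),
            p_value=opt(row, "p_value", float),
            allele_frequency=opt(row, "allele_frequency", float),
        ))
    return records


def _variant_key(rec: VariantRecord):
    if rec.chromosome is not None and rec.position is not None:
        return (str(rec.chromosome), int(rec.position),
                frozenset((rec.effect_allele, rec.other_allele)))
    return rec.variant_id


def _orient(rec: VariantRecord, ref: VariantRecord, band: float) -> VariantRecord | None:
    """Return ``rec`` oriented to ``ref``'s effect allele, or None to drop.

    Handles allele swaps (sign flip), strand flips (complemented alleles),
    and palindromic A/T / C/G pairs, which are oriented by allele frequency
    when it is informative and dropped otherwise.
    """
    ea, oa = rec.effect_allele, rec.other_allele
    r_ea, r_oa = ref.effect_allele, ref.other_allele
    cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")

    def flipped() -> VariantRecord:
        af = None if rec.allele_frequency is None else 1.0 - rec.allele_frequency
        return replace(rec, effect_allele=r_ea, other_allele=r_oa,
                       effect=-rec.effect, allele_frequency=af)

    def same() -> VariantRecord:
        return replace(rec, effect_allele=r_ea, other_allele=r_oa)

    if rec.is_palindromic:
        # Strand cannot be resolved from alleles alone. Drop inside the
        # ambiguous frequency band; outside it, orient by frequency.
        for r in (rec, ref):
            if r.allele_frequency is None or band <= r.allele_frequency <= 1 - band:
                return None
        if {ea, oa} != {r_ea, r_oa}:
            return None
        aligned = same() if ea == r_ea else flipped()
        # opposite minor-allele side implies the strand (hence sign) flipped
        if (aligned.allele_frequency < 0.5) != (ref.allele_frequency < 0.5):
            af = 1.0 - aligned.allele_frequency
            aligned = replace(aligned, effect=-aligned.effect, allele_frequency=af)
        return aligned

    if (ea, oa) == (r_ea, r_oa) or (cea, coa) == (r_ea, r_oa):
        return same()
    if (oa, ea) == (r_ea, r_oa) or (coa, cea) == (r_ea, r_oa):
        return flipped()
    return None  # allele sets irreconcilable


def _chrom_sort_value(c: str) -> tuple:
    s = str(c).removeprefix("chr")
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


def harmonize_records(
    panels: Sequence[Sequence[VariantRecord]],
    ambiguous_af_band: float = 0.40,
) -> list[list[VariantRecord]]:
    """Intersect and allele-align studies at the record level.

    Returns one list per retained variant, ordered (chromosome, position)
    when coordinates exist, each containing the aligned records for every
    study in input order. This is the workhorse behind :func:`harmonize`
    and is idempotent: re-aligning its own output changes nothing.
    """
    if len(panels) < 2:
        raise ValueError("harmonize needs at least one exposure and one outcome study")
    maps = [{_variant_key(r): r for r in panel} for panel in panels]
    shared = set(maps[0])
    for mp in maps[1:]:
        shared &= set(mp)
    if not shared:
        raise EmptyIntersectionError("no variant is shared by all studies")

    rows = []
    for key in shared:
        ref = maps[0][key]
        if ref.is_palindromic and _orient(ref, ref, ambiguous_af_band) is None:
            continue
        oriented = [ref]
        ok = True
        for mp in maps[1:]:
            o = _orient(mp[key], ref, ambiguous_af_band)
            if o is None:
                ok = False
                break
            oriented.append(o)
        if ok:
            rows.append(oriented)
    if not rows:
        raise EmptyIntersectionError(
            "all shared variants were dropped during allele alignment")

    ref0 = rows[0][0]
    if ref0.chromosome is not None and ref0.position is not None:
        rows.sort(key=lambda r: (_chrom_sort_value(r[0].chromosome), r[0].position))
    else:
        rows.sort(key=lambda r: r[0].variant_id)
    return rows


def harmonize(
    panels: Sequence[Sequence[VariantRecord]],
    exposure_names: Sequence[str] | None = None,
    ambiguous_af_band: float = 0.40,
) -> HarmonizedPanel:
    """Intersect and allele-align p+1 studies into one panel.

    ``panels`` holds the p exposure studies followed by the outcome study
    (last element). The first study is the allele reference. Variants are
    keyed on (chromosome, position, allele set), falling back to variant_id
    when coordinates are absent. Strand-ambiguous (A/T, C/G) variants whose
    allele frequency falls inside ``[ambiguous_af_band, 1-ambiguous_af_band]``
    in any study are dropped. Output rows are sorted by (chromosome,
    position) when coordinates exist, else by variant_id.
    """
    rows = harmonize_records(panels, ambiguous_af_band)
    p = len(panels) - 1
    names = list(exposure_names) if exposure_names else [f"exposure{k + 1}" for k in range(p)]
    if len(names) != p:
        raise ValueError("exposure_names length must equal the exposure count")

    def grid(attr, studies, cast=float):
        vals = [[getattr(r, attr) for r in row] for row in rows]
        arr = np.array([[np.nan if vals[i][j] is None else cast(vals[i][j])
                         for j in studies] for i in range(len(rows))], dtype=float)
        return arr

    exp_idx, out_idx = list(range(p)), [p]
    exp_n = grid("sample_size", exp_idx)
    out_n = grid("sample_size", out_idx)[:, 0]
    exp_p = grid("p_value", exp_idx)
    out_p = grid("p_value", out_idx)[:, 0]
    have_coords = all(row[0].chromosome is not None and row[0].position is not None
                      for row in rows)
    return HarmonizedPanel(
        variant_ids=[row[0].variant_id for row in rows],
        exposure_estimates=grid("effect", exp_idx),
        outcome_estimates=grid("effect", out_idx)[:, 0],
        exposure_ses=grid("standard_error", exp_idx),
        outcome_ses=grid("standard_error", out_idx)[:, 0],
        exposure_names=names,
        chromosomes=(np.array([str(row[0].chromosome) for row in rows])
                     if have_coords else None),
        positions=(np.array([int(row[0].position) for row in rows])
                   if have_coords else None),
        exposure_n=None if np.isnan(exp_n).all() else exp_n,
        outcome_n=None if np.isnan(out_n).all() else out_n,
        exposure_pvalues=None if np.isnan(exp_p).all() else exp_p,
        outcome_pvalues=None if np.isnan(out_p).all() else out_p,
    )


def standardize(panel: HarmonizedPanel, mode: str = "by_se_sqrt_n") -> HarmonizedPanel:
    """Place all estimates on a common scale.

    ``by_se_sqrt_n`` maps each estimate to z/√n = effect/(SE·√n) with SE
    1/√n, the standardized-trait scale on which the true variance of every
    estimate is the reciprocal GWAS sample size. ``by_se_only`` maps each
    estimate to its z-score with SE 1 (used when sample sizes are wildly
    unequal across studies and a per-√n scale would distort effect sizes).
    """
    if panel.standardization != "none":
        raise StandardizationStateError(
            f"panel is already standardized ({panel.standardization})")
    if mode == "none":
        return panel
    if mode not in ("by_se_sqrt_n", "by_se_only"):
        raise ValueError(f"unknown standardization mode {mode!r}")

    if mode == "by_se_sqrt_n":
        if (panel.exposure_n is None or panel.outcome_n is None
                or np.isnan(panel.exposure_n).any() or np.isnan(panel.outcome_n).any()):
            raise StandardizationStateError(
                "by_se_sqrt_n requires sample sizes for every study and variant")
        sqn_x = np.sqrt(panel.exposure_n)
        sqn_y = np.sqrt(panel.outcome_n)
        exposure = panel.exposure_estimates / (panel.exposure_ses * sqn_x)
        outcome = panel.outcome_estimates / (panel.outcome_ses * sqn_y)
        exposure_ses = 1.0 / sqn_x
        outcome_ses = 1.0 / sqn_y
    else:
        exposure = panel.exposure_estimates / panel.exposure_ses
        outcome = panel.outcome_estimates / panel.outcome_ses
        exposure_ses = np.ones_like(panel.exposure_ses)
        outcome_ses = np.ones_like(panel.outcome_ses)

    out = panel.subset(np.arange(panel.m))
    out.exposure_estimates = exposure
    out.outcome_estimates = outcome
    out.exposure_ses = exposure_ses
    out.outcome_ses = outcome_ses
    out.standardization = mode
    return out


def _min_exposure_p(panel: HarmonizedPanel) -> np.ndarray:
    if panel.exposure_pvalues is not None and not np.isnan(panel.exposure_pvalues).any():
        pv = panel.exposure_pvalues
    else:
        z = np.abs(panel.exposure_estimates / panel.exposure_ses)
        pv = 2.0 * stats.norm.sf(z)
    return pv.min(axis=1)


def select_instruments(
    panel: HarmonizedPanel,
    p_threshold: float = 5e-8,
    window_bp: int = 1_000_000,
) -> HarmonizedPanel:
    """Threshold-and-prune instrument selection.

    Keeps variants whose minimum exposure p-value is below ``p_threshold``,
    then greedily prunes by distance: survivors are visited in ascending
    order of that minimum p-value and kept only when no already-kept variant
    lies within ``window_bp`` on the same chromosome (a stand-in for LD
    clumping when no reference panel is available).
    """
    minp = _min_exposure_p(panel)
    sig = np.flatnonzero(minp < p_threshold)
    if sig.size == 0:
        raise EmptySelectionError(
            f"no variant passes the exposure p-value threshold {p_threshold:g}")
    order = sig[np.argsort(minp[sig], kind="stable")]
    if panel.chromosomes is None or panel.positions is None:
        kept = sorted(order)
    else:
        kept = []
        for i in order:
            ci, xi = panel.chromosomes[i], panel.positions[i]
            if all(panel.chromosomes[j] != ci or abs(int(panel.positions[j]) - int(xi)) > window_bp
                   for j in kept):
                kept.append(i)
        kept.sort()
    return panel.subset(np.asarray(kept))
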