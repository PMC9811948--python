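"""End-to-end study pipeline: ingest a cohort, apply the exclusion flow,
score the composite, summarise demographics, run the validation statistics
battery and the missing-data audit, and emit a machine-readable report.

The pipeline operates on lists of :class:`~mcogscore.synthetic.ParticipantRecord`
(either simulated or loaded from the roster/items CSV interface) and keeps
every number at full precision; presentation rounding is applied only by the
text renderer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import IntegrityError, SchemaError, UndefinedStatisticError
from .roc import LabelledScores, bootstrap_auc_ci, delong_paired, empirical_roc, youden_cutoff
from .scoring import SUBTESTS, MemoryItem, StroopTrial, SymbolTrial, composite_mcog, fit_reference
from .stats import (
    ContingencyTable2x2,
    chi2_2x2,
    mann_whitney,
    proportional_median_difference,
    shapiro_wilk,
    spearman,
    two_sample_t,
)
from .synthetic import (
    EDUCATION_LEVELS,
    ITEM_COLUMNS,
    ROSTER_COLUMNS,
    ParticipantRecord,
    missingness_report,
)

REPORT_SCHEMA_VERSION = "1.0"

Disposition = Literal["included", "revoked_consent", "cdr_gt_1", "upload_failed", "incomplete_mcog"]
EXCLUSION_ORDER: tuple[Disposition, ...] = (
    "revoked_consent", "cdr_gt_1", "upload_failed", "incomplete_mcog")


# --------------------------------------------------------------------------
# ingestion


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def _parse_bool(value: str, line: int, errors: list[str]) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    errors.append(f"line {line}: cannot parse boolean {value!r}")
    return False


def load_cohort(roster_csv: str | Path, items_csv: str | Path) -> list[ParticipantRecord]:
    """Read and validate the roster and item-response CSVs.

    Empty response cells are parsed as skipped items, never as zeros.
    Raises :class:`SchemaError` for missing columns and
    :class:`IntegrityError` (with offending line numbers) for duplicate ids
    or out-of-range values.
    """
    roster = pd.read_csv(roster_csv, dtype=str, keep_default_na=False)
    items = pd.read_csv(items_csv, dtype=str, keep_default_na=False)
    _require_columns(roster, ROSTER_COLUMNS, "roster CSV")
    _require_columns(items, ITEM_COLUMNS, "items CSV")

    errors: list[str] = []
    dup = roster["participant_id"][roster["participant_id"].duplicated()]
    if not dup.empty:
        raise IntegrityError(f"duplicate participant_id(s): {sorted(set(dup))}",
                             [f"line {i + 2}" for i in dup.index])

    items_by_pid = {pid: grp for pid, grp in items.groupby("participant_id")}
    records: list[ParticipantRecord] = []
    for idx, row in roster.iterrows():
        line = idx + 2  # header is line 1
        pid = row["participant_id"]
        revoked = _parse_bool(row["revoked_consent"], line, errors)
        uploaded = _parse_bool(row["uploaded"], line, errors)

        def opt_float(col: str) -> float | None:
            v = row[col].strip()
            return float(v) if v != "" else None

        cdr = opt_float("cdr_global")
        if cdr is not None and cdr not in (0.0, 0.5, 1.0, 2.0, 3.0):
            errors.append(f"line {line}: cdr_global {cdr} outside {{0, 0.5, 1, 2, 3}}")
        mmse_raw = row["mmse2_total"].strip()
        mmse = None
        if mmse_raw != "":
            mmse = int(float(mmse_raw))
            if not 0 <= mmse <= 30:
                errors.append(f"line {line}: mmse2_total {mmse} outside [0, 30]")
        education = row["education"].strip() or None
        if education is not None and education not in EDUCATION_LEVELS:
            errors.append(f"line {line}: education {education!r} not in {EDUCATION_LEVELS}")
        sex = row["sex"].strip() or None
        if sex is not None and sex not in ("M", "F"):
            errors.append(f"line {line}: sex {sex!r} not in ('M', 'F')")

        stroop = symbols = memory = None
        if pid in items_by_pid:
            try:
                stroop, symbols, memory = _parse_items(items_by_pid[pid])
            except (ValueError, KeyError) as exc:
                errors.append(f"participant {pid}: {exc}")
        records.append(ParticipantRecord(
            participant_id=pid, cdr_global=cdr, age=opt_float("age"), sex=sex,
            education=education, mmse2_total=mmse, stroop_trials=stroop,
            symbol_trials=symbols, memory_items=memory,
            uploaded=uploaded, revoked_consent=revoked,
        ))
    if errors:
        raise IntegrityError(f"{len(errors)} row-level validation error(s); first: {errors[0]}", errors)
    return records


def _parse_items(grp: pd.DataFrame) -> tuple[list[StroopTrial], list[SymbolTrial], list[MemoryItem]]:
    stroop: list[StroopTrial] = []
    sub = grp[grp["subtest"] == "stroop"].sort_values("item_index", key=lambda s: s.astype(int))
    for _, r in sub.iterrows():
        resp = r["response"].strip() or None
        rt = float(r["response_time_s"]) if r["response_time_s"].strip() else None
        stroop.append(StroopTrial(r["stimulus"], r["correct_response"], resp, rt))

    symbols: list[SymbolTrial] = []
    sub = grp[grp["subtest"] == "symbols"].sort_values("item_index", key=lambda s: s.astype(int))
    for _, r in sub.iterrows():
        resp = int(r["response"]) if r["response"].strip() else None
        rt = float(r["response_time_s"]) if r["response_time_s"].strip() else None
        symbols.append(SymbolTrial(int(r["stimulus"]), int(r["correct_response"]), resp, rt))

    memory: list[MemoryItem] = []
    sub = grp[grp["subtest"] == "memory"]
    for idx in sorted(sub["item_index"].astype(int).unique()):
        item_rows = {r["phase"]: r for _, r in sub[sub["item_index"].astype(int) == idx].iterrows()}
        imm, dly = item_rows["immediate"], item_rows["delayed"]
        first_opts = tuple(imm["options"].split("|"))
        second_opts = tuple(dly["options"].split("|"))
        fc = first_opts.index(imm["response"]) if imm["response"].strip() else None
        sc = second_opts.index(dly["response"]) if dly["response"].strip() else None
        memory.append(MemoryItem(imm["stimulus"], first_opts, second_opts, fc, sc))
    return stroop, symbols, memory


# --------------------------------------------------------------------------
# exclusion flow


@dataclass(frozen=True)
class ExclusionLedger:
    """Each participant's disposition, assigned in the fixed priority order
    revoked consent > CDR > 1 > upload failure > incomplete triplet."""

    dispositions: dict[str, Disposition]

    @property
    def counts(self) -> dict[str, int]:
        out = {"included": 0, **{c: 0 for c in EXCLUSION_ORDER}}
        for d in self.dispositions.values():
            out[d] += 1
        return out

    @property
    def total(self) -> int:
        return len(self.dispositions)


def apply_exclusions(roster: Sequence[ParticipantRecord]) -> tuple[list[ParticipantRecord], ExclusionLedger]:
    """Partition the consented roster into included participants and the
    exclusion ledger. Included participants have CDR in {0, 0.5, 1},
    uploaded data, and a complete three-subtest triplet; a participant
    matching several exclusion reasons is counted once, at the highest-
    priority reason."""
    dispositions: dict[str, Disposition] = {}
    included: list[ParticipantRecord] = []
    for rec in roster:
        if rec.revoked_consent:
            dispositions[rec.participant_id] = "revoked_consent"
        elif rec.cdr_global is None or rec.cdr_global > 1:
            dispositions[rec.participant_id] = "cdr_gt_1"
        elif not rec.uploaded or rec.stroop_trials is None:
            dispositions[rec.participant_id] = "upload_failed"
        else:
            results = rec.subtest_results()
            if all(r.completed for r in results.values()):
                dispositions[rec.participant_id] = "included"
                included.append(rec)
            else:
                dispositions[rec.participant_id] = "incomplete_mcog"
    return included, ExclusionLedger(dispositions)


# --------------------------------------------------------------------------
# scoring


def score_cohort(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Score every participant with uploaded item data.

    The z-reference is fitted on the participants in ``records`` with
    complete triplets (self-referenced norms), so pass the included roster
    to reproduce the study's analysis. Returns one row per scoreable
    participant with raw scores, z-scores, composite and status.
    """
    rows = []
    triplets = []
    for rec in records:
        results = rec.subtest_results()
        if results is None:
            continue
        rows.append((rec, results))
        if all(r.completed for r in results.values()):
            triplets.append(tuple(results[k].raw_score for k in SUBTESTS))
    reference = fit_reference(triplets)
    out = []
    for rec, results in rows:
        comp = composite_mcog(results["stroop"], results["symbols"], results["memory"], reference)
        out.append({
            "participant_id": rec.participant_id,
            "impaired": rec.impaired,
            "mmse2_total": rec.mmse2_total,
            "raw_stroop": comp.raw_stroop, "raw_symbols": comp.raw_symbols, "raw_memory": comp.raw_memory,
            "z_stroop": comp.z_stroop, "z_symbols": comp.z_symbols, "z_memory": comp.z_memory,
            "m_cogscore": comp.m_cogscore, "status": comp.status,
        })
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# summaries and statistics


def _numeric_summary(values: np.ndarray) -> dict:
    """mean/sd/median/IQR/min/max with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "min": float(v.min()), "max": float(v.max()),
    }


def table1_summary(included: Sequence[ParticipantRecord], scores: pd.DataFrame | None = None) -> dict:
    """Per-group demographic and score summary (the study's Table 1 shape)."""
    if scores is None:
        scores = score_cohort(included)
    scores = scores.set_index("participant_id")
    out = {}
    for group, flag in (("healthy", False), ("impaired", True)):
        recs = [r for r in included if r.impaired is flag]
        if not recs:
            raise UndefinedStatisticError(f"no participants in the {group} group")
        ages = np.array([r.age for r in recs])
        mmse = np.array([r.mmse2_total for r in recs], dtype=float)
        comp = scores.loc[[r.participant_id for r in recs], "m_cogscore"].to_numpy(dtype=float)
        out[group] = {
            "n": len(recs),
            "sex": {"M": sum(r.sex == "M" for r in recs), "F": sum(r.sex == "F" for r in recs)},
            "education": {lvl: sum(r.education == lvl for r in recs) for lvl in EDUCATION_LEVELS},
            "age": _numeric_summary(ages),
            "mmse2": _numeric_summary(mmse),
            "m_cogscore": _numeric_summary(comp),
        }
    return out


_EDU_ORDINAL = {lvl: i + 1 for i, lvl in enumerate(EDUCATION_LEVELS)}


def run_validation(
    included: Sequence[ParticipantRecord],
    scores: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    boot_proportion: float = 0.75,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> dict:
    """The validation statistics battery on the included cohort.

    Normality gates (Shapiro-Wilk) are recorded as metadata only; the
    reported comparisons are always the rank-based ones, keeping outputs
    comparable across cohorts. Emits Spearman convergent validity, the
    group comparisons, proportional median differences, both ROC curves
    with Youden cut-offs and proportion-bootstrap CIs, and the paired
    DeLong comparison.
    """
    if scores is None:
        scores = score_cohort(included)
    complete = scores[scores["status"] == "complete"]
    labels = complete["impaired"].astype(int).to_numpy()
    mmse = complete["mmse2_total"].to_numpy(dtype=float)
    comp = complete["m_cogscore"].to_numpy(dtype=float)
    healthy, impaired = labels == 0, labels == 1

    block: dict = {"n": int(labels.size)}
    block["normality"] = {
        "mmse2": shapiro_wilk(mmse).as_dict(),
        "m_cogscore": shapiro_wilk(comp).as_dict(),
    }
    block["spearman_mcog_mmse"] = spearman(comp, mmse).as_dict()

    block["group_comparisons"] = {
        "mmse2_mwu": mann_whitney(mmse[healthy], mmse[impaired]).as_dict(),
        "m_cogscore_mwu": mann_whitney(comp[healthy], comp[impaired]).as_dict(),
        "age_ttest": two_sample_t(
            [r.age for r in included if not r.impaired],
            [r.age for r in included if r.impaired]).as_dict(),
        "education_mwu": mann_whitney(
            [_EDU_ORDINAL[r.education] for r in included if not r.impaired],
            [_EDU_ORDINAL[r.education] for r in included if r.impaired]).as_dict(),
    }
    block["proportional_median_difference"] = {
        "mmse2": proportional_median_difference(
            float(np.median(mmse[healthy])), float(np.median(mmse[impaired])),
            float(mmse.max()), float(mmse.min())),
        "m_cogscore": proportional_median_difference(
            float(np.median(comp[healthy])), float(np.median(comp[impaired])),
            float(comp.max()), float(comp.min())),
    }

    roc_block = {}
    for name, values in (("m_cogscore", comp), ("mmse2", mmse)):
        data = LabelledScores(values, labels, direction="lower")
        roc = empirical_roc(data)
        cut = youden_cutoff(roc)
        ci = bootstrap_auc_ci(data, n_boot=n_boot, proportion=boot_proportion,
                              alpha=alpha, seed=seed)
        roc_block[name] = {
            "auc": roc.auc,
            "ci": {"lower": ci.lower, "upper": ci.upper, "alpha": ci.alpha,
                   "n_boot": ci.n_boot, "proportion": ci.proportion},
            "cutoff": {"threshold": cut.threshold, "sensitivity": cut.sensitivity,
                       "specificity": cut.specificity, "youden_j": cut.youden_j,
                       "rule": "score < threshold predicts impaired"},
        }
    dl = delong_paired(comp, mmse, labels, direction="lower")
    roc_block["delong"] = {
        "auc_m_cogscore": dl.auc_a, "auc_mmse2": dl.auc_b,
        "delta": dl.auc_a - dl.auc_b, "z": dl.z, "p": dl.p_two_sided,
    }
    block["roc"] = roc_block
    return block


def missing_data_analysis(
    roster: Sequence[ParticipantRecord],
    ledger: ExclusionLedger,
) -> dict:
    """Audit of excluded participants against the included cohort.

    Reports per-subtest skip counts by group, age and MMSE comparisons
    between excluded and included participants, and the two impaired-
    proportion contingency comparisons (all-missing vs included,
    incomplete-subgroup vs included) with Yates-corrected chi-squared.
    """
    by_id = {r.participant_id: r for r in roster}
    included = [by_id[p] for p, d in ledger.dispositions.items() if d == "included"]
    incomplete = [by_id[p] for p, d in ledger.dispositions.items() if d == "incomplete_mcog"]
    upload_failed = [by_id[p] for p, d in ledger.dispositions.items() if d == "upload_failed"]
    missing = incomplete + upload_failed  # participants lacking a complete triplet

    block: dict = {
        "skip_counts": missingness_report(roster).to_dict(),
        "n_missing": len(missing),
        "n_incomplete": len(incomplete),
        "n_upload_failed": len(upload_failed),
    }
    if not missing:
        block["applicable"] = False
        return block
    block["applicable"] = True

    def impaired_count(recs):
        return sum(1 for r in recs if r.impaired)

    comparisons: dict = {}
    inc_ages = [r.age for r in included if r.age is not None]
    mis_ages = [r.age for r in missing if r.age is not None]
    if len(mis_ages) >= 2:
        comparisons["age_ttest_missing_vs_included"] = two_sample_t(mis_ages, inc_ages).as_dict()
    inc_mmse = [r.mmse2_total for r in included if r.mmse2_total is not None]
    mis_mmse = [r.mmse2_total for r in missing if r.mmse2_total is not None]
    if mis_mmse:
        comparisons["mmse2_mwu_missing_vs_included"] = mann_whitney(mis_mmse, inc_mmse).as_dict()

    for key, subset in (("all_missing", missing), ("incomplete_subgroup", incomplete)):
        n_imp, n_tot = impaired_count(subset), len(subset)
        table = ContingencyTable2x2(
            ((n_imp, n_tot - n_imp),
             (impaired_count(included), len(included) - impaired_count(included))),
            row_labels=(key, "included"), col_labels=("impaired", "healthy"),
        )
        comparisons[f"impaired_proportion_{key}"] = {
            "table": [list(r) for r in table.counts],
            **chi2_2x2(table, yates=True).as_dict(),
        }
    block["comparisons"] = comparisons
    return block


# --------------------------------------------------------------------------
# report assembly


@dataclass
class StudyReport:
    """Machine-readable study report with provenance."""

    table1: dict
    validation: dict
    missingness: dict
    exclusions: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "exclusions": self.exclusions,
            "table1": self.table1,
            "validation": self.validation,
            "missingness": self.missingness,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def build_report(
    roster: Sequence[ParticipantRecord],
    n_boot: int = 10_000,
    boot_proportion: float = 0.75,
    alpha: float = 0.05,
    seed: int | None = 0,
    provenance: dict | None = None,
) -> StudyReport:
    """Run the whole analysis on a consented roster and assemble the report."""
    included, ledger = apply_exclusions(roster)
    scores = score_cohort(included)
    prov = {"package_version": __version__, "seed": seed, "n_boot": n_boot,
            "boot_proportion": boot_proportion, **(provenance or {})}
    return StudyReport(
        table1=table1_summary(included, scores),
        validation=run_validation(included, scores, n_boot=n_boot,
                                  boot_proportion=boot_proportion, alpha=alpha, seed=seed),
        missingness=missing_data_analysis(roster, ledger),
        exclusions={"counts": ledger.counts, "total": ledger.total},
        provenance=prov,
    )


def config_hash(config_json: str) -> str:
    return hashlib.sha256(config_json.encode()).hexdigest()[:16]


def render_report(report: dict) -> str:
    """Human-readable summary with presentation rounding (1 d.p. for
    chi-squared, 2 d.p. for rho / AUC / p-values)."""
    lines = []
    exc = report["exclusions"]["counts"]
    lines.append(f"Participants: {report['exclusions']['total']} consented, "
                 f"{exc['included']} included "
                 f"(revoked {exc['revoked_consent']}, CDR>1 {exc['cdr_gt_1']}, "
                 f"upload failed {exc['upload_failed']}, incomplete {exc['incomplete_mcog']})")
    for group in ("healthy", "impaired"):
        t = report["table1"][group]
        lines.append(
            f"  {group}: n={t['n']}, age {t['age']['mean']:.1f}±{t['age']['sd']:.1f}, "
            f"MMSE-2 {t['mmse2']['mean']:.1f}±{t['mmse2']['sd']:.1f}, "
            f"composite {t['m_cogscore']['mean']:.2f}±{t['m_cogscore']['sd']:.2f}")
    val = report["validation"]
    sp = val["spearman_mcog_mmse"]
    lines.append(f"Convergent validity: rho = {sp['value']:.2f} (p = {sp['p']:.2g})")
    for name, label in (("m_cogscore", "Composite"), ("mmse2", "MMSE-2")):
        r = val["roc"][name]
        lines.append(
            f"{label}: AUC = {r['auc']:.2f} "
            f"[{r['ci']['lower']:.2f}, {r['ci']['upper']:.2f}], "
            f"cut-off < {r['cutoff']['threshold']:.2f} "
            f"(sens {r['cutoff']['sensitivity']:.2f}, spec {r['cutoff']['specificity']:.2f})")
    dl = val["roc"]["delong"]
    lines.append(f"DeLong comparison: ΔAUC = {dl['delta']:.2f}, p = {dl['p']:.2f}")
    mis = report["missingness"]
    if mis.get("applicable"):
        c = mis["comparisons"]["impaired_proportion_incomplete_subgroup"]
        lines.append(f"Missing-data audit: {mis['n_missing']} without complete data; "
                     f"incomplete-subgroup chi-squared = {c['value']:.1f} (p = {c['p']:.2f})")
    return "\n".join(lines)
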