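"""Synthetic cohort and amplicon-read generator.

Generates cohorts whose statistical structure matches the triple-negative
breast cancer MRD study conditions the package targets: per-tumor somatic
variant counts with median 77.5 and a heavy right tail clipped to [1, 1970],
86% of tumors carrying a non-silent TP53 variant, tumor-tissue VAFs
centered on 32.9% against baseline blood VAFs centered on 0.33%, a
T0 / Cycle-1-Day-3 / surgery / every-6-months draw schedule with imperfect
compliance, relapse trajectories whose molecular onset precedes clinical
relapse by a uniform 2-7 month lead time, and UMI-tagged paired-end
amplicon reads with configurable per-base error.

Every stochastic choice is recorded in a :class:`TruthRecord` so downstream
stages (panel design, UMI consensus, VAF quantification, MRD monitoring)
can be verified against ground truth.  Two fidelity levels are provided:

* per-locus template counts (``simulate_locus_counts``) - binomial draws of
  alt template molecules, the exact quantity the zero-error read path
  recovers; cheap enough for cohort-scale end-to-end runs; and
* full UMI-tagged FASTQ read pairs (``simulate_amplicon_reads``) for
  exercising the consensus machinery itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panel_design import PanelDesign, SomaticVariant
from .vaf_quant import LocusReadcount

_GENE_POOL = (
    "PIK3CA NF1 RB1 PTEN RECQL4 TNC MYC NOTCH1 KMT2C ARID1A GATA3 AKT1 "
    "CDH1 MAP3K1 RUNX1 NCOR1 TBX3 FOXA1 CTCF SF3B1 USH2A MUC16 SYNE1 "
    "DNAH5 RYR2 FAT3 CSMD3 LRP1B PCDH15 SPTA1"
).split()
_NONSILENT = ("missense", "nonsense", "frameshift", "splice", "other_nonsilent")
_CHROMS = [str(c) for c in range(1, 23)] + ["X"]
_BASES4 = "ACGT"


class ConfigurationError(ValueError):
    """Raised for invalid cohort or error-model configuration."""


@dataclass(frozen=True)
class CountLaw:
    """Log-normal law for per-tumor somatic variant counts, hard-clipped.

    ``location`` is the log-scale median (ln 77.5 by default), ``spread``
    the log-scale standard deviation; draws are rounded and clipped to
    [lo, hi] = [1, 1970].
    """

    location: float = math.log(77.5)
    spread: float = 1.1
    lo: int = 1
    hi: int = 1970

    def __post_init__(self) -> None:
        if self.lo > self.hi or self.lo < 1 or self.spread <= 0:
            raise ConfigurationError("invalid variant count law")

    def sample(self, rng: np.random.Generator) -> int:
        x = int(round(float(rng.lognormal(self.location, self.spread))))
        return int(np.clip(x, self.lo, self.hi))


def default_draw_schedule(
    surgery_month: float = 5.0,
    c1d3_month: float = 0.1,
    interval_months: float = 6.0,
    followup_months: float = 48.0,
) -> list[tuple[str, float]]:
    """T0 baseline, T1 at Cycle 1 Day 3, T2 at surgery, then T3.k every
    ``interval_months`` until end of follow-up."""
    sched = [("T0", 0.0), ("T1", c1d3_month), ("T2", surgery_month)]
    k, month = 1, surgery_month + interval_months
    while month <= followup_months:
        sched.append((f"T3.{k}", month))
        k += 1
        month += interval_months
    return sched


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for cohort simulation.

    Defaults emulate the 50-patient cohort this package models: 14% clinical
    relapse, 34% pathological complete response, 86% TP53-mutant tumors,
    tumor-tissue VAF mean 32.9%, baseline blood VAF mean 0.33%, draws at T0 /
    C1D3 / surgery (month 5) / every 6 months to month 48, 2-7 month
    molecular lead times, and the study-like evaluability failure modes
    (undetectable baseline < 0.05%, apparent germline variants at ~100%
    blood VAF, missed draws).
    """

    n_patients: int = 50
    relapse_rate: float = 0.14
    pcr_rate: float = 0.34
    variant_count_law: CountLaw = field(default_factory=CountLaw)
    tp53_prob: float = 0.86
    tissue_vaf_mean: float = 0.329
    tissue_vaf_concentration: float = 8.0
    blood_vaf_mean_baseline: float = 0.0033
    blood_vaf_log_sd: float = 0.8
    c1d3_multiplier: float = 1.5
    lead_time_range: tuple[float, float] = (2.0, 7.0)
    relapse_onset_vaf: float = 5e-4
    relapse_peak_vaf: float = 0.02
    surgery_month: float = 5.0
    followup_months: float = 48.0
    draw_interval_months: float = 6.0
    draw_compliance: float = 0.8
    low_baseline_prob: float = 0.08
    germline_artifact_prob: float = 0.04
    transient_positive_prob_pcr: float = 0.1
    transient_positive_prob_non_pcr: float = 0.35
    transient_vaf: float = 2e-4
    low_probe_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.relapse_rate, self.pcr_rate, self.tp53_prob,
            self.draw_compliance, self.low_baseline_prob,
            self.germline_artifact_prob, self.transient_positive_prob_pcr,
            self.transient_positive_prob_non_pcr, self.low_probe_prob,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must be in [0, 1]")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.followup_months <= 0:
            raise ConfigurationError("followup_months must be > 0")
        if not self.lead_time_range[0] <= self.lead_time_range[1]:
            raise ConfigurationError("lead_time_range must be ordered")
        if not self.draw_schedule():
            raise ConfigurationError("draw schedule is empty")

    def draw_schedule(self) -> list[tuple[str, float]]:
        return default_draw_schedule(
            self.surgery_month, 0.1, self.draw_interval_months,
            self.followup_months,
        )


@dataclass(frozen=True)
class ErrorModel:
    """Read-level error model for amplicon simulation.

    ``templates_per_amplicon`` defaults to desk scale (5,000 template
    molecules per amplicon, configurable up to production depth); family
    sizes are shifted Poisson (1 + Poisson(family_size_mean - 1), so every
    template yields at least one read pair).
    """

    per_base_substitution_rate: float = 0.001
    no_call_rate: float = 0.0
    umi_length: int = 10
    read_length: int = 150
    family_size_mean: float = 4.0
    templates_per_amplicon: int = 5000

    def __post_init__(self) -> None:
        for name in ("per_base_substitution_rate", "no_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if self.umi_length < 1 or self.templates_per_amplicon < 1:
            raise ConfigurationError("umi_length and templates must be >= 1")
        if self.family_size_mean < 1:
            raise ConfigurationError("family_size_mean must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth for one simulated patient."""

    patient_id: str
    variant_profile: list[SomaticVariant]
    pcr: bool
    surgery_month: float
    clinical_relapse_month: float | None
    molecular_onset_month: float | None
    trajectory: dict[str, float]                  # label -> tumor signal fraction
    draws: list[tuple[str, float, bool]]          # (label, month, occurred)
    variant_multipliers: dict[tuple, float]
    germline_locus: tuple | None = None
    transient_label: str | None = None
    transient_locus: tuple | None = None
    transient_vaf_value: float = 0.0
    lead_time_clamped: bool = False
    category_truth: str = "evaluable"

    def occurred_draws(self) -> list[tuple[str, float]]:
        return [(lab, m) for lab, m, occ in self.draws if occ]

    def true_locus_vaf(self, locus: tuple, label: str) -> float:
        """True blood allele fraction of one panel locus at one draw."""
        if self.germline_locus is not None and locus == self.germline_locus:
            return 0.99
        signal = self.trajectory.get(label, 0.0)
        vaf = signal * self.variant_multipliers.get(locus, 1.0)
        if self.transient_label == label and locus == self.transient_locus:
            vaf += self.transient_vaf_value
        return float(min(vaf, 1.0))

    def expected_category(
        self,
        loci: list[tuple] | None = None,
        baseline_threshold: float = 5e-4,
        germline_threshold: float = 0.90,
    ) -> str:
        """Evaluability label implied by the true VAFs at the occurred draws.

        ``loci`` restricts the rule to the patient's designed panel; by
        default the whole variant profile is used.  Mirrors the monitoring
        classifier's precedence exactly.
        """
        occurred = self.occurred_draws()
        if not occurred:
            return "insufficient_data"
        if loci is None:
            loci = [v.locus for v in self.variant_profile]
        for lab, _ in occurred:
            if any(
                self.true_locus_vaf(loc, lab) >= germline_threshold
                for loc in loci
            ):
                return "germline_artifact"
        labels = {lab for lab, _ in occurred}
        if "T0" not in labels:
            return "insufficient_data"
        if not any(m >= self.surgery_month for _, m in occurred):
            return "insufficient_data"
        baseline_max = max(
            (self.true_locus_vaf(loc, "T0") for loc in loci), default=0.0
        )
        if baseline_max < baseline_threshold:
            return "low_baseline_signal"
        return "evaluable"


def simulate_variant_profile(
    cfg: CohortConfig, rng: np.random.Generator, patient_id: str
) -> list[SomaticVariant]:
    """Draw one tumor's somatic variant profile.

    Counts follow the clipped log-normal law; tissue VAFs are Beta-
    distributed around ``tissue_vaf_mean``; a non-silent TP53 variant is
    present with probability ``tp53_prob`` (occasionally more than one); a
    minority of variants carry filter-failing covariates so the somatic
    filters have work to do, with the TP53 (or top) variant always passing.
    """
    n = cfg.variant_count_law.sample(rng)
    has_tp53 = rng.random() < cfg.tp53_prob
    n_tp53 = 0
    if has_tp53:
        n_tp53 = min(1 + rng.binomial(2, 0.12), n)

    m = cfg.tissue_vaf_mean
    k = cfg.tissue_vaf_concentration
    a, b = m * k, (1 - m) * k

    positions: list[int] = []
    seen: set[int] = set()
    while len(positions) < n:
        p = int(rng.integers(10_000, 200_000_000))
        if p not in seen:
            seen.add(p)
            positions.append(p)
    variants: list[SomaticVariant] = []
    for i in range(n):
        is_tp53 = i < n_tp53
        gene = "TP53" if is_tp53 else _GENE_POOL[int(rng.integers(len(_GENE_POOL)))]
        chrom = "17" if is_tp53 else _CHROMS[int(rng.integers(len(_CHROMS)))]
        ref = _BASES4[int(rng.integers(4))]
        alt = _BASES4[(int(_BASES4.index(ref)) + 1 + int(rng.integers(3))) % 4]
        if is_tp53:
            cons = _NONSILENT[int(rng.integers(len(_NONSILENT)))]
        else:
            cons = (
                "silent"
                if rng.random() < 0.25
                else _NONSILENT[int(rng.integers(len(_NONSILENT)))]
            )
        # filter covariates; ~12% of non-anchor variants fail some filter
        known = (not is_tp53) and rng.random() < 0.03
        pop_af = 0.05 if ((not is_tp53) and rng.random() < 0.04) else 0.0
        mq0 = 0.30 if ((not is_tp53) and rng.random() < 0.03) else float(
            rng.uniform(0, 0.05)
        )
        depth = int(rng.poisson(73)) + 1
        if is_tp53 or i == n_tp53:  # anchor variant always passes filters
            known, pop_af, mq0 = False, 0.0, float(rng.uniform(0, 0.05))
            depth = max(depth, 25)
        conf = "low" if ((not is_tp53) and rng.random() < 0.04) else "high"
        variants.append(
            SomaticVariant(
                patient_id=patient_id,
                chrom=chrom,
                pos=int(positions[i]),
                ref_allele=ref,
                alt_allele=alt,
                gene_symbol=gene,
                consequence_class=cons,
                tissue_vaf=float(rng.beta(a, b)),
                depth=depth,
                population_af=pop_af,
                mq0_fraction=mq0,
                known_variant=known,
                confidence=conf,
            )
        )
    return variants


def simulate_trajectory(
    cfg: CohortConfig,
    rng: np.random.Generator,
    relapse_month: float | None,
    lead_time: float | None,
    low_baseline: bool,
    schedule: list[tuple[str, float]],
) -> tuple[dict[str, float], float | None, bool]:
    """True tumor-signal fraction at each scheduled draw.

    Baseline signal is log-normal with mean ``blood_vaf_mean_baseline``
    (or uniformly below the detectability threshold for low-baseline
    patients); C1D3 scales baseline by ``c1d3_multiplier``; the signal is
    zero from surgery onward except for relapse patients, whose signal
    rises exponentially from ``relapse_onset_vaf`` at molecular onset
    (clinical relapse minus lead time, clamped to surgery at the earliest)
    to ``relapse_peak_vaf`` at clinical relapse.

    Returns (trajectory, molecular onset month, whether the lead time was
    clamped at surgery).
    """
    mu = math.log(cfg.blood_vaf_mean_baseline) - cfg.blood_vaf_log_sd**2 / 2
    if low_baseline:
        baseline = float(rng.uniform(1e-5, 3e-4))
    else:
        baseline = float(rng.lognormal(mu, cfg.blood_vaf_log_sd))

    onset = None
    clamped = False
    if relapse_month is not None:
        onset = relapse_month - (lead_time or 0.0)
        if onset < cfg.surgery_month:
            onset = cfg.surgery_month
            clamped = True

    traj: dict[str, float] = {}
    for label, month in schedule:
        if month < cfg.surgery_month:
            sig = baseline * (cfg.c1d3_multiplier if label == "T1" else 1.0)
        elif onset is not None and month >= onset:
            # exponential rise from onset to peak at clinical relapse
            span = max(relapse_month - onset, 1e-9)
            frac = min((month - onset) / span, 1.0)
            sig = cfg.relapse_onset_vaf * (
                (cfg.relapse_peak_vaf / cfg.relapse_onset_vaf) ** frac
            )
        else:
            sig = 0.0
        traj[label] = float(min(sig, 1.0))
    if relapse_month is not None:
        traj["T4"] = cfg.relapse_peak_vaf
    return traj, onset, clamped


def simulate_cohort(config: CohortConfig) -> list[TruthRecord]:
    """Simulate a full cohort with ground truth.

    Deterministic in ``config.seed``; relapse and pCR are independent
    Bernoulli draws at the configured rates.
    """
    rng = np.random.default_rng(config.seed)
    schedule = config.draw_schedule()
    records: list[TruthRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        pcr = bool(rng.random() < config.pcr_rate)
        relapse = bool(rng.random() < config.relapse_rate)
        low_baseline = rng.random() < config.low_baseline_prob
        germline = rng.random() < config.germline_artifact_prob

        profile = simulate_variant_profile(config, rng, pid)

        relapse_month = None
        lead = None
        if relapse:
            lo = config.surgery_month + 2.0
            relapse_month = float(rng.uniform(lo, config.followup_months))
            lead = float(rng.uniform(*config.lead_time_range))

        traj, onset, clamped = simulate_trajectory(
            config, rng, relapse_month, lead, low_baseline, schedule
        )

        # draws: scheduled ones before clinical relapse, plus T4 at relapse
        draws: list[tuple[str, float, bool]] = []
        for label, month in schedule:
            if relapse_month is not None and month >= relapse_month:
                continue
            draws.append((label, month, bool(rng.random() < config.draw_compliance)))
        if relapse_month is not None:
            draws.append(
                ("T4", relapse_month, bool(rng.random() < config.draw_compliance))
            )

        mults = {
            v.locus: float(rng.uniform(0.6, 1.4)) for v in profile
        }

        # the variant guaranteed to enter the panel: top non-silent TP53,
        # else the overall top-VAF variant
        tp53s = [v for v in profile if v.is_nonsilent_tp53]
        anchor = max(
            tp53s or profile, key=lambda v: (v.tissue_vaf, v.depth)
        )

        truth = TruthRecord(
            patient_id=pid,
            variant_profile=profile,
            pcr=pcr,
            surgery_month=config.surgery_month,
            clinical_relapse_month=relapse_month,
            molecular_onset_month=onset,
            trajectory=traj,
            draws=draws,
            variant_multipliers=mults,
            germline_locus=anchor.locus if germline else None,
            lead_time_clamped=clamped,
            transient_vaf_value=config.transient_vaf,
        )

        if relapse_month is None:
            p_trans = (
                config.transient_positive_prob_pcr
                if pcr
                else config.transient_positive_prob_non_pcr
            )
            if rng.random() < p_trans:
                post = [
                    (lab, m)
                    for lab, m, occ in draws
                    if occ and m >= config.surgery_month and lab != "T4"
                ]
                if post:
                    lab, _ = post[int(rng.integers(len(post)))]
                    truth.transient_label = lab
                    truth.transient_locus = anchor.locus

        truth.category_truth = truth.expected_category()
        records.append(truth)
    return records


# ---------------------------------------------------------------------------
# amplicon sequence attachment and read simulation
# ---------------------------------------------------------------------------

_CODE_TO_BYTE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def attach_amplicon_sequences(
    panel: PanelDesign, rng: np.random.Generator
) -> dict[str, str]:
    """Generate a random reference sequence per amplicon.

    The reference base at the variant offset equals the variant's ref
    allele; 5' anchor prefixes (first 20 bp) are unique across the panel so
    anchor-based read assignment is unambiguous.
    """
    seqs: dict[str, str] = {}
    anchors: set[str] = set()
    for t in panel.targets:
        length = t.amplicon_end - t.amplicon_start
        while True:
            codes = rng.integers(0, 4, size=length)
            seq = "".join(_BASES4[c] for c in codes)
            seq = (
                seq[: t.locus_offset]
                + t.variant.ref_allele
                + seq[t.locus_offset + len(t.variant.ref_allele):]
            )
            if seq[:20] not in anchors:
                anchors.add(seq[:20])
                break
        seqs[t.amplicon_id] = seq
    return seqs


def _decode_rows(mat: np.ndarray) -> list[str]:
    rows = _CODE_TO_BYTE[mat]
    return [r.tobytes().decode("ascii") for r in rows]


def simulate_amplicon_reads(
    panel: PanelDesign,
    amplicon_seqs: dict[str, str],
    locus_alt_fraction: dict[str, float],
    error_model: ErrorModel,
    rng: np.random.Generator,
    read_id_prefix: str = "sim",
) -> tuple[list[tuple], dict[str, dict]]:
    """Simulate UMI-tagged paired reads for one sample over one panel.

    Per amplicon, the number of alt template molecules is Binomial(
    ``templates_per_amplicon``, locus alt fraction).  Every template gets a
    distinct UMI (drawn without replacement) prepended to read 2 and a
    family of 1 + Poisson(mean - 1) read pairs; substitution and no-call
    noise is applied per base to both reads (including the UMI bases of
    read 2).  Read 1 carries the full amplicon sequence.

    Returns ``(read_pairs, truth)`` where each read pair is
    (read_id, r1_seq, r1_qual, r2_seq, r2_qual) and truth maps amplicon_id
    to its template/alt-template/read-pair counts.
    """
    em = error_model
    read_pairs: list[tuple] = []
    truth: dict[str, dict] = {}
    qual1 = "?" * em.read_length
    serial = 0
    for t in panel.targets:
        amp_id = t.amplicon_id
        seq = amplicon_seqs[amp_id]
        if not 0 <= t.locus_offset < len(seq):
            raise ConfigurationError(
                f"variant locus outside amplicon {amp_id}"
            )
        length = min(len(seq), em.read_length)
        ref_codes = np.array(
            [_BASES4.index(b) for b in seq[:length]], dtype=np.uint8
        )
        af = float(locus_alt_fraction.get(amp_id, 0.0))
        n_templ = em.templates_per_amplicon
        n_alt = int(rng.binomial(n_templ, af)) if af > 0 else 0

        # UMIs come from a parity-check code (last base balances the base
        # sum mod 4): distinct templates then differ in >= 2 UMI positions,
        # so error-free reads are never merged across templates, while
        # single sequencing errors in a UMI remain correctable by
        # directional grouping -- mirroring error-distinguishable vendor
        # UMI sets.
        umi_space = 4 ** (em.umi_length - 1)
        umi_ints = rng.choice(umi_space, size=n_templ, replace=False)
        fam_sizes = 1 + rng.poisson(em.family_size_mean - 1.0, size=n_templ)
        total = int(fam_sizes.sum())

        templ_mat = np.tile(ref_codes, (n_templ, 1))
        if n_alt:
            alt_code = _BASES4.index(t.variant.alt_allele)
            templ_mat[:n_alt, t.locus_offset] = alt_code

        read_idx = np.repeat(np.arange(n_templ), fam_sizes)
        r1 = templ_mat[read_idx].copy()
        r1 = _apply_noise(r1, em, rng)

        # read 2: UMI + template prefix, truncated to read_length
        umis = _umi_codes(umi_ints, em.umi_length)
        r2_len = min(em.read_length, em.umi_length + length)
        r2 = np.concatenate(
            [umis[read_idx], templ_mat[read_idx][:, : r2_len - em.umi_length]],
            axis=1,
        )
        r2 = _apply_noise(r2, em, rng)

        r1_strs = _decode_rows(r1)
        r2_strs = _decode_rows(r2)
        qual2 = "?" * r2.shape[1]
        q1 = "?" * r1.shape[1]
        for j in range(total):
            read_pairs.append(
                (f"{read_id_prefix}:{serial}", r1_strs[j], q1, r2_strs[j], qual2)
            )
            serial += 1
        truth[amp_id] = {
            "templates": n_templ,
            "alt_templates": n_alt,
            "read_pairs": total,
        }
    return read_pairs, truth


def _umi_codes(umi_ints: np.ndarray, umi_length: int) -> np.ndarray:
    """Base-4 digits of each int over the first umi_length - 1 positions,
    plus a parity base making the column sum 0 mod 4."""
    out = np.empty((len(umi_ints), umi_length), dtype=np.uint8)
    vals = umi_ints.astype(np.int64)
    for j in range(umi_length - 2, -1, -1):
        out[:, j] = vals % 4
        vals //= 4
    out[:, umi_length - 1] = (-out[:, : umi_length - 1].sum(axis=1)) % 4
    return out


def _apply_noise(
    mat: np.ndarray, em: ErrorModel, rng: np.random.Generator
) -> np.ndarray:
    if em.per_base_substitution_rate > 0:
        sub = rng.random(mat.shape) < em.per_base_substitution_rate
        shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
        mat = np.where(sub & (mat < 4), (mat + shift) % 4, mat)
    if em.no_call_rate > 0:
        nc = rng.random(mat.shape) < em.no_call_rate
        mat = np.where(nc, np.uint8(4), mat)
    return mat


def simulate_locus_counts(
    truth: TruthRecord,
    panel: PanelDesign,
    label: str,
    error_model: ErrorModel,
    rng: np.random.Generator,
    low_probe_prob: float = 0.0,
) -> list[LocusReadcount]:
    """Count-level sample simulation (no reads).

    Per panel locus, the alt consensus count is Binomial(templates, true
    locus VAF) - exactly what the zero-error read path recovers - with raw
    coverage templates x mean family size.  With probability
    ``low_probe_prob`` a probe is low-performing: raw coverage below 1,000x
    and proportionally fewer consensus molecules.
    """
    out = []
    for t in panel.targets:
        v = t.variant
        templates = error_model.templates_per_amplicon
        raw = int(round(templates * error_model.family_size_mean))
        if low_probe_prob > 0 and rng.random() < low_probe_prob:
            raw = int(rng.integers(0, 1000))
            templates = max(int(raw / error_model.family_size_mean), 0)
        af = truth.true_locus_vaf(v.locus, label)
        alt = int(rng.binomial(templates, af)) if templates and af > 0 else 0
        out.append(
            LocusReadcount(
                patient_id=truth.patient_id,
                timepoint=label,
                chrom=v.chrom,
                pos=v.pos,
                ref_allele=v.ref_allele,
                alt_allele=v.alt_allele,
                ref_count=templates - alt,
                alt_count=alt,
                other_count=0,
                no_call_count=0,
                raw_coverage=raw,
            )
        )
    return out
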