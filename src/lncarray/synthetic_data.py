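"""Seeded synthetic study generator with stored ground truth.

Emulates the structure of a 3'-array lncRNA mining study: a transcript
reference with probe sets lifted from it (optionally corrupted by single-base
mismatches or copied into a second transcript to trigger the uniqueness
criterion), probe-level log2 intensities with planted tumor/normal shifts, a
latent co-expression factor tied to one target transcript, clinical
covariates drawn conditionally on the target's median split, and exponential
survival times with a planted log-hazard for the high-expression group.

Everything is a deterministic function of (parameters, seed): one global
``numpy.random.SeedSequence(seed)`` spawns one child stream per component.
The returned truth object records every planted parameter so downstream
recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .association import median_split
from .expression import probe_row_id
from .reannotation import ProbeRecord, TranscriptRecord

__all__ = [
    "SyntheticTruth",
    "SyntheticReference",
    "SyntheticStudy",
    "generate_reference",
    "generate_study",
    "generate_gene_sets",
    "paperlike_covariate_links",
    "simulate_paperlike",
    "write_study",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Planted parameters sufficient to recompute every expected outcome."""

    probeset_map: Dict[str, str] = field(default_factory=dict)
    mismatched_probes: List[Tuple[str, int]] = field(default_factory=list)
    ambiguous_probes: List[Tuple[str, int]] = field(default_factory=list)
    de_effects: Dict[str, float] = field(default_factory=dict)
    baselines: Dict[str, float] = field(default_factory=dict)
    target_transcript: Optional[str] = None
    coexpressed: List[str] = field(default_factory=list)
    coexpression_strength: float = 0.0
    covariate_links: Dict[str, dict] = field(default_factory=dict)
    beta_survival: float = 0.0
    censoring_fraction: float = 0.0
    noise_sd: float = 0.0
    seeds: Dict[str, int] = field(default_factory=dict)

    def expected_assignments(self, min_probes: int = 4) -> Dict[str, str]:
        """Probeset -> transcript map a perfect re-annotation should recover.

        A probe contributes only if it was neither mismatched (matches
        nothing) nor duplicated into a second transcript (fails the
        uniqueness criterion); a set is expected assigned iff its clean
        probe count reaches ``min_probes``.
        """
        bad: Dict[str, set] = {}
        for psid, idx in [*self.mismatched_probes, *self.ambiguous_probes]:
            bad.setdefault(psid, set()).add(idx)
        out = {}
        for psid, tid in self.probeset_map.items():
            n_probes = self._probes_per_set.get(psid, 0)
            clean = n_probes - len(bad.get(psid, ()))
            if clean >= min_probes:
                out[psid] = tid
        return out

    _probes_per_set: Dict[str, int] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


@dataclass
class SyntheticReference:
    transcripts: List[TranscriptRecord]
    probes: List[ProbeRecord]
    truth: SyntheticTruth


@dataclass
class SyntheticStudy:
    probe_expr: pd.DataFrame  # probe rows ("ps:idx") x samples, log2 scale
    clinical: pd.DataFrame  # indexed by sample_id: cohort + covariates
    survival: pd.DataFrame  # tumor samples: time_months, event, group
    split: pd.Series  # low/high labels for tumor samples (target median split)
    truth: SyntheticTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _spawn_seeds(seed: Optional[int], names: Sequence[str]) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_reference(
    n_transcripts: int = 60,
    lnc_fraction: float = 0.5,
    length_range: Tuple[int, int] = (400, 1200),
    n_probesets: int = 40,
    probes_per_set: int = 11,
    probe_len: int = 25,
    mismatch_rate: float = 0.0,
    ambiguous_rate: float = 0.0,
    seed: Optional[int] = None,
) -> SyntheticReference:
    """Generate a transcript reference and probe sets lifted from it.

    Each probe set's probes are exact substrings of its source transcript at
    distinct offsets.  A ``mismatch_rate`` fraction of probes get one random
    base substitution (so they no longer match anywhere); an
    ``ambiguous_rate`` fraction are additionally copied into a decoy
    transcript without a probe set of its own (so they match two transcripts
    and fail the uniqueness criterion).  The truth records the planted map
    and every injection.
    """
    if probe_len > length_range[0]:
        raise ValueError("probe_len exceeds the minimum transcript length")
    if n_probesets > n_transcripts:
        raise ValueError("cannot source more probe sets than transcripts")
    if ambiguous_rate > 0 and n_probesets >= n_transcripts:
        raise ValueError(
            "ambiguous_rate > 0 needs decoy transcripts: require n_probesets < n_transcripts"
        )
    if not (0 <= mismatch_rate <= 1 and 0 <= ambiguous_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rngs = _spawn_seeds(seed, ["sequences", "probes", "injections"])
    rng = rngs["sequences"]

    n_lnc = int(round(lnc_fraction * n_transcripts))
    seqs = {}
    transcripts = []
    for i in range(n_transcripts):
        tid = f"TX{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seqs[tid] = _random_seq(rng, length)
        transcripts.append(
            TranscriptRecord(
                tid,
                seqs[tid],
                gene_symbol=f"GENE{i:04d}",
                biotype="lncRNA" if i < n_lnc else "protein_coding",
            )
        )

    rng_p = rngs["probes"]
    rng_i = rngs["injections"]
    source_ids = [t.transcript_id for t in transcripts[:n_probesets]]
    decoy_ids = [t.transcript_id for t in transcripts[n_probesets:]]
    truth = SyntheticTruth(seeds={"global": -1 if seed is None else int(seed)})
    probes: List[ProbeRecord] = []
    mutated_seqs = dict(seqs)
    occupied: Dict[str, List[Tuple[int, int]]] = {d: [] for d in decoy_ids}
    for k, tid in enumerate(source_ids):
        psid = f"PS{k:04d}_at"
        truth.probeset_map[psid] = tid
        truth._probes_per_set[psid] = probes_per_set
        max_off = len(seqs[tid]) - probe_len
        offsets = sorted(rng_p.choice(max_off + 1, size=probes_per_set, replace=False))
        for j, off in enumerate(offsets):
            probe_seq = seqs[tid][off : off + probe_len]
            if rng_i.random() < mismatch_rate:
                pos = int(rng_i.integers(probe_len))
                old = probe_seq[pos]
                new = str(rng_i.choice([b for b in "ACGT" if b != old]))
                probe_seq = probe_seq[:pos] + new + probe_seq[pos + 1 :]
                truth.mismatched_probes.append((psid, j))
            elif ambiguous_rate > 0 and rng_i.random() < ambiguous_rate:
                # place the copy where it cannot clobber an earlier copy
                for _ in range(200):
                    host = str(rng_i.choice(decoy_ids))
                    hseq = mutated_seqs[host]
                    hoff = int(rng_i.integers(len(hseq) - probe_len + 1))
                    if all(
                        hoff + probe_len <= a or hoff >= b for a, b in occupied[host]
                    ):
                        break
                else:  # pragma: no cover - would need saturated decoys
                    raise ValueError("could not place ambiguous probe copy; too few decoys")
                occupied[host].append((hoff, hoff + probe_len))
                mutated_seqs[host] = hseq[:hoff] + probe_seq + hseq[hoff + probe_len :]
                truth.ambiguous_probes.append((psid, j))
            probes.append(ProbeRecord(psid, j, probe_seq))
    transcripts = [
        dataclasses.replace(t, sequence=mutated_seqs[t.transcript_id]) for t in transcripts
    ]
    return SyntheticReference(transcripts, probes, truth)


def _censoring_horizon(rates: np.ndarray, fraction: float) -> float:
    """Upper bound of the Uniform(0, u) censoring time giving the target
    expected censoring fraction for a mixture of exponential event times."""

    def censored_frac(u: float) -> float:
        lam_u = rates * u
        return float(np.mean((1.0 - np.exp(-lam_u)) / lam_u))

    return brentq(lambda u: censored_frac(u) - fraction, 1e-9, 1e9)


def generate_study(
    reference: SyntheticReference,
    n_tumor: int = 226,
    n_normal: int = 50,
    de_transcripts: Optional[Dict[str, float]] = None,
    noise_sd: float = 0.4,
    covariate_links: Optional[Dict[str, dict]] = None,
    beta_survival: float = 0.0,
    censoring_fraction: float = 0.5,
    target_transcript: Optional[str] = None,
    coexpressed: Optional[Sequence[str]] = None,
    coexpression_strength: float = 0.8,
    baseline_half_life_months: float = 50.0,
    seed: Optional[int] = None,
) -> SyntheticStudy:
    """Generate probe-level expression, clinical covariates and survival.

    Probe intensities are transcript baseline (U(6, 10) log2 units) plus the
    planted tumor/normal shift from ``de_transcripts``, with independent
    N(0, ``noise_sd``) probe noise; the target transcript additionally
    carries an N(0, 1) per-sample latent deviation so its median split is
    informative.  Tumor samples are median-split on the target transcript's
    realized (probe-median) expression; ``coexpressed`` transcripts are
    raised by ``coexpression_strength`` log2 units in the high-split samples
    (emulating genes co-regulated with the target); categorical covariates
    are drawn from the group-conditional level probabilities in
    ``covariate_links`` (``{"levels": [...],
    "p_low": [...], "p_high": [...]}``, or ``{"mean_low", "mean_high",
    "sd"}`` for continuous), and survival times are exponential with rate
    ``log(2)/baseline_half_life_months * exp(beta_survival * 1[high])``,
    censored by an independent Uniform(0, u) mechanism with u solved to hit
    ``censoring_fraction`` in expectation.  Normals carry no covariates or
    survival.  Deterministic given (parameters, seed).
    """
    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need at least 2 samples per arm")
    if not 0 <= censoring_fraction < 1:
        raise ValueError("censoring_fraction must be in [0, 1)")
    de_transcripts = dict(de_transcripts or {})
    covariate_links = dict(covariate_links or {})
    for name, link in covariate_links.items():
        if "levels" in link:
            for key in ("p_low", "p_high"):
                p = np.asarray(link[key], dtype=float)
                if (p < 0).any() or (p > 1).any() or not np.isclose(p.sum(), 1.0):
                    raise ValueError(f"covariate {name!r}: {key} is not a probability vector")

    truth = dataclasses.replace(reference.truth, seeds=dict(reference.truth.seeds))
    rngs = _spawn_seeds(seed, ["expression", "covariates", "survival"])
    rng = rngs["expression"]

    probesets = sorted(truth.probeset_map)
    tids = [truth.probeset_map[ps] for ps in probesets]
    if target_transcript is None:
        target_transcript = tids[0]
    coexpressed = list(coexpressed or [])

    samples = [f"N{i:04d}" for i in range(n_normal)] + [f"T{i:04d}" for i in range(n_tumor)]
    cohort = np.array(["normal"] * n_normal + ["tumor"] * n_tumor)
    n_samples = len(samples)
    is_tumor = cohort == "tumor"

    baselines = {tid: float(b) for tid, b in zip(sorted(set(tids)), rng.uniform(6, 10, len(set(tids))))}
    latent = rng.normal(0.0, 1.0, n_samples)

    def base_mu(tid: str) -> np.ndarray:
        mu = np.full(n_samples, baselines[tid])
        if tid in de_transcripts:
            mu = mu + de_transcripts[tid] * is_tumor
        if tid == target_transcript:
            mu = mu + latent
        return mu

    probes_by_set: Dict[str, list] = {}
    for p in reference.probes:
        probes_by_set.setdefault(p.probeset_id, []).append(p)

    # target probe rows first: the realized target expression (probe median
    # over tumor samples) defines the low/high split that the co-expressed
    # transcripts, covariates and survival all condition on
    probe_rows: Dict[str, np.ndarray] = {}
    target_sets = [ps for ps in probesets if truth.probeset_map[ps] == target_transcript]
    for psid in target_sets:
        for p in sorted(probes_by_set[psid], key=lambda q: q.probe_index):
            probe_rows[probe_row_id(psid, p.probe_index)] = base_mu(
                target_transcript
            ) + rng.normal(0.0, noise_sd, n_samples)
    target_value = pd.DataFrame(probe_rows, index=samples).T.median(axis=0)
    tumor_ids = [s for s, t in zip(samples, is_tumor) if t]
    split = median_split(target_value[tumor_ids])
    is_high = (split == "high").to_numpy()
    high_indicator = pd.Series(0.0, index=samples)
    high_indicator.loc[split.index[is_high]] = 1.0

    for psid in probesets:
        tid = truth.probeset_map[psid]
        if tid == target_transcript:
            continue
        mu = base_mu(tid)
        if tid in coexpressed:
            mu = mu + coexpression_strength * high_indicator.to_numpy()
        for p in sorted(probes_by_set[psid], key=lambda q: q.probe_index):
            probe_rows[probe_row_id(psid, p.probe_index)] = mu + rng.normal(
                0.0, noise_sd, n_samples
            )
    ordered = [
        probe_row_id(psid, p.probe_index)
        for psid in probesets
        for p in sorted(probes_by_set[psid], key=lambda q: q.probe_index)
    ]
    probe_expr = pd.DataFrame(
        np.array([probe_rows[r] for r in ordered]), index=ordered, columns=samples
    )

    rng_c = rngs["covariates"]
    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clinical["cohort"] = cohort
    for name in sorted(covariate_links):
        link = covariate_links[name]
        col = pd.Series(pd.NA, index=clinical.index, dtype=object)
        if "levels" in link:
            levels = list(link["levels"])
            draws = [
                str(rng_c.choice(levels, p=link["p_high"] if hi else link["p_low"]))
                for hi in is_high
            ]
        else:
            mus = np.where(is_high, link["mean_high"], link["mean_low"])
            draws = mus + rng_c.normal(0.0, link["sd"], len(tumor_ids))
        col.loc[tumor_ids] = draws
        clinical[name] = col

    rng_s = rngs["survival"]
    base_rate = np.log(2.0) / baseline_half_life_months
    rates = base_rate * np.exp(beta_survival * is_high.astype(float))
    times = rng_s.exponential(1.0 / rates)
    if censoring_fraction > 0:
        horizon = _censoring_horizon(rates, censoring_fraction)
        cens = rng_s.uniform(0.0, horizon, len(times))
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(len(times), dtype=int)
        obs = times
    survival = pd.DataFrame(
        {
            "time_months": np.maximum(obs, 1e-6),
            "event": event,
            "group": split.to_numpy(),
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )

    truth.de_effects = de_transcripts
    truth.baselines = baselines
    truth.target_transcript = target_transcript
    truth.coexpressed = list(coexpressed)
    truth.coexpression_strength = float(coexpression_strength if coexpressed else 0.0)
    truth.covariate_links = covariate_links
    truth.beta_survival = float(beta_survival)
    truth.censoring_fraction = float(censoring_fraction)
    truth.noise_sd = float(noise_sd)
    truth.seeds["study"] = -1 if seed is None else int(seed)
    return SyntheticStudy(probe_expr, clinical, survival, split, truth)


def generate_gene_sets(
    reference: SyntheticReference,
    n_sets: int = 20,
    set_size: int = 15,
    seed: Optional[int] = None,
    planted_set: Optional[Sequence[str]] = None,
    exclude: Optional[Sequence[str]] = None,
) -> Dict[str, Set[str]]:
    """Random gene-set collection over the reference's gene symbols.

    ``planted_set`` (gene symbols, e.g. the co-expressed block) is included
    under the name ``"PLANTED_COEXPRESSED"``.  Symbols in ``exclude`` (by
    default the planted symbols, so the random sets are genuinely null) are
    withheld from the random sets.
    """
    rng = np.random.default_rng(seed)
    exclude_set = set(exclude if exclude is not None else (planted_set or []))
    symbols = sorted(
        {t.gene_symbol for t in reference.transcripts if t.gene_symbol} - exclude_set
    )
    sets: Dict[str, Set[str]] = {}
    for i in range(n_sets):
        size = min(set_size, len(symbols))
        sets[f"RANDOM_SET_{i:03d}"] = set(rng.choice(symbols, size=size, replace=False))
    if planted_set:
        sets["PLANTED_COEXPRESSED"] = set(planted_set)
    return sets


def paperlike_covariate_links() -> Dict[str, dict]:
    """Covariate link parameters mirroring the printed Table 1 proportions
    (low vs high target expression in a 226-sample adenocarcinoma cohort)."""
    return {
        "age_years": {"mean_low": 56.0, "mean_high": 59.2, "sd": 7.0},
        "gender": {"levels": ["male", "female"], "p_low": [0.513, 0.487], "p_high": [0.416, 0.584]},
        "smoking": {"levels": ["yes", "no"], "p_low": [0.540, 0.460], "p_high": [0.442, 0.558]},
        "tnm_stage": {
            "levels": ["Ia", "Ib", "II"],
            "p_low": [0.363, 0.239, 0.398],
            "p_high": [0.646, 0.239, 0.115],
        },
        "alk_fusion": {"levels": ["yes", "no"], "p_low": [0.062, 0.938], "p_high": [0.035, 0.965]},
        "egfr_mutation": {"levels": ["yes", "no"], "p_low": [0.540, 0.460], "p_high": [0.336, 0.664]},
        "kras_mutation": {"levels": ["yes", "no"], "p_low": [0.115, 0.885], "p_high": [0.071, 0.929]},
        "myc_expression": {"levels": ["high", "low"], "p_low": [0.071, 0.929], "p_high": [0.080, 0.920]},
    }


def simulate_paperlike(seed: Optional[int] = None, out_dir: Optional[Union[str, Path]] = None):
    """One-call synthetic study shaped like the source cohorts.

    226 tumors + 50 normals over a 60-transcript reference with 40 probe
    sets of 11 25-nt probes; the target lncRNA transcript is down-shifted
    2 log2 units in tumors, 12 transcripts co-express with it (strength 0.8),
    Table 1-style covariate links, survival log-hazard log(0.48) for the
    high group with 50% censoring.  Returns (reference, study, gene_sets)
    and, when ``out_dir`` is given, writes every pipeline input file there.
    """
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    reference = generate_reference(
        n_transcripts=60,
        lnc_fraction=0.5,
        n_probesets=40,
        probes_per_set=11,
        mismatch_rate=0.05,
        ambiguous_rate=0.05,
        seed=int(seeds[0]),
    )
    target = reference.truth.probeset_map["PS0000_at"]
    coexpressed_tids = [reference.truth.probeset_map[f"PS{k:04d}_at"] for k in range(1, 13)]
    symbols = {t.transcript_id: t.gene_symbol for t in reference.transcripts}
    study = generate_study(
        reference,
        n_tumor=226,
        n_normal=50,
        de_transcripts={target: -2.0},
        noise_sd=0.4,
        covariate_links=paperlike_covariate_links(),
        beta_survival=float(np.log(0.48)),
        censoring_fraction=0.5,
        target_transcript=target,
        coexpressed=coexpressed_tids,
        seed=int(seeds[1]),
    )
    gene_sets = generate_gene_sets(
        reference,
        n_sets=20,
        set_size=12,
        seed=int(seeds[2]),
        planted_set=[symbols[t] for t in coexpressed_tids],
        exclude=[symbols[t] for t in coexpressed_tids] + [symbols[target]],
    )
    if out_dir is not None:
        write_study(reference, study, gene_sets, out_dir)
    return reference, study, gene_sets


def write_study(
    reference: SyntheticReference,
    study: SyntheticStudy,
    gene_sets: Dict[str, Set[str]],
    out_dir: Union[str, Path],
) -> Dict[str, Path]:
    """Write all pipeline input files (FASTA, probe-tab, TSVs, GMT, truth JSON)."""
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_fasta": out / "reference.fasta",
        "biotype_tsv": out / "biotypes.tsv",
        "probe_tab": out / "probes.tsv",
        "probe_expr_tsv": out / "probe_expression.tsv",
        "clinical_tsv": out / "clinical.tsv",
        "survival_tsv": out / "survival.tsv",
        "gmt": out / "gene_sets.gmt",
        "truth_json": out / "truth.json",
    }
    io.write_transcripts(reference.transcripts, paths["reference_fasta"], paths["biotype_tsv"])
    io.write_probe_tab(reference.probes, paths["probe_tab"])
    io.write_expression_matrix(study.probe_expr, paths["probe_expr_tsv"])
    study.clinical.to_csv(paths["clinical_tsv"], sep="\t", na_rep="NA")
    study.survival.reset_index().to_csv(paths["survival_tsv"], sep="\t", index=False)
    io.write_gene_sets(gene_sets, paths["gmt"])
    study.truth.to_json(paths["truth_json"])
    return paths
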