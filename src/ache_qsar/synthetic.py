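"""Synthetic fixtures for every pipeline stage: molecules, raw activity
tables with curation hazards, and responses with a planted additive signal.

Three generators cover the pipeline:

* :func:`gen_molecules` builds a library of valid, standardization-stable
  SMILES from a fragment grammar biased toward cholinesterase-inhibitor
  chemotypes (piperidine, benzene, indole, pyrazole, tetrahydroacridine
  scaffolds joined by aliphatic/ether linkers).
* :func:`gen_activity_table` emits a raw ChEMBL-style export with replicate
  rows, inequality qualifiers, mixed units and missing cells at configured
  rates, together with its own ground-truth bookkeeping of which compounds a
  correct curation chain must retain.
* :func:`gen_response` plants an additive structure-activity signal on count
  fingerprints with Gaussian noise of known variance, so the achievable
  ceiling Q2max = var(signal) / var(y) is analytic.

:func:`gen_chembl_like_table` combines these into a full-scale emulation of a
ChEMBL-20 acetylcholinesterase extract whose composition plan realizes the
canonical curation survivor counts.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import from_pic50, standardize_structure

# ---------------------------------------------------------------------------
# fragment grammar

# {R} marks the substitution slot.  Ring-closure digits 1-4 are reserved for
# depth-1 fragments; nested fragments get digits shifted to 5-8.
_SCAFFOLDS = [
    "c1ccc({R})cc1",              # benzene
    "C1CCN({R})CC1",              # N-substituted piperidine
    "C1CCC({R})CC1",              # cyclohexane
    "c1ccc2c(c1)c({R})c[nH]2",    # 3-substituted indole
    "c1cc({R})[nH]n1",            # pyrazole
    "O=C({R})N1CCCCC1",           # piperidine amide
]
_TERMINALS = [
    "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "Cl", "F", "C#N", "C(F)(F)F", "C(C)C", "C(=O)O", "C(=O)NC",
    "[N+](=O)[O-]", "S(=O)(=O)N", "C=C",
]
_LINKERS = ["", "C", "CC", "CCC", "CCCC", "OC", "OCC", "C(=O)", "CN(C)C", "COC"]
# acyclic, non-aromatic molecules guarantee the grammar also produces
# structures matching neither the aromatic nor the heterocyclic pattern
_PLAIN = ["CCCCCC", "CCCCCCC", "CCOCC", "CCCCO", "CC(C)CC(C)C", "CCCC(=O)OCC",
          "NCCCCN", "CCCCC#N", "OCCOCCO", "CC(C)(C)CC"]
_TACRINE = "Nc1c2c(nc3ccccc13)CCCC2"  # tetrahydroacridine (tacrine) core

_SHIFT = str.maketrans("1234", "5678")


def _compose(rng: np.random.Generator, depth: int = 0) -> str:
    scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
    if depth > 0:
        scaffold = scaffold.translate(_SHIFT)
    linker = _LINKERS[rng.integers(len(_LINKERS))]
    if depth == 0 and rng.random() < 0.35:
        inner = _compose(rng, depth=1)
    else:
        inner = _TERMINALS[rng.integers(len(_TERMINALS))]
    return scaffold.replace("{R}", linker + inner)


def gen_molecules(n: int, seed: int = 0, canonical_tautomer: bool = True) -> list[str]:
    """Generate ``n`` distinct, standardized, parseable SMILES strings.

    Deterministic under ``seed``.  Returned SMILES are already standardized,
    so a second pass through the standardizer leaves them unchanged.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    # seed the library with the guaranteed chemotype anchors
    for smi in [_TACRINE] + _PLAIN:
        std = standardize_structure(smi, canonical_tautomer=canonical_tautomer)
        if std not in seen:
            seen.add(std)
            out.append(std)
            if len(out) == n:
                return out
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("fragment grammar exhausted before reaching n molecules")
        smi = _compose(rng)
        if Chem.MolFromSmiles(smi) is None:
            continue
        try:
            std = standardize_structure(smi, canonical_tautomer=canonical_tautomer)
        except ValueError:
            continue
        if std and std not in seen:
            seen.add(std)
            out.append(std)
    return out


# ---------------------------------------------------------------------------
# raw activity tables

RECORD_COLUMNS = ["compound_id", "smiles", "endpoint", "qualifier", "value", "unit"]


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for a synthetic raw activity table.

    Rates are per-record (qualifier, missing value, units) or per-compound
    (replicates, noisy replicate groups, missing SMILES).  ``noise_sd`` is the
    compound-level Gaussian noise on the true pIC50 in log units;
    ``replicate_jitter`` is the measurement-level spread among replicates of
    one compound.
    """

    n_compounds: int = 500
    replicate_rate: float = 0.2
    qualifier_rate: float = 0.0
    missing_rate: float = 0.0
    missing_smiles_rate: float = 0.0
    noisy_replicate_rate: float = 0.0
    unit_mix: dict = field(default_factory=lambda: {"nM": 1.0})
    planted_features: tuple = ()
    noise_sd: float = 0.0
    replicate_jitter: float = 0.15
    pic50_mean: float = 6.0
    pic50_sd: float = 1.2
    seed: int = 0

    def __post_init__(self):
        for name in ("replicate_rate", "qualifier_rate", "missing_rate",
                     "missing_smiles_rate", "noisy_replicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(sum(self.unit_mix.values()) - 1.0) > 1e-9:
            raise ValueError("unit_mix proportions must sum to 1")


def gen_activity_table(spec: SynthSpec, smiles: list[str] | None = None):
    """Emit a raw activity table with hazards, plus ground-truth bookkeeping.

    Returns ``(records, truth)`` where ``records`` is a raw-table DataFrame
    (one row per measurement, generic dialect) and ``truth`` one row per
    compound with the generator's own verdict: ``survives`` and, for
    survivors, the exact pIC50 a correct curation chain must report
    (arithmetic mean of the pIC50 of its clean nM records).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    if smiles is None:
        smiles = gen_molecules(min(n, 400), seed=spec.seed + 1)
    units = list(spec.unit_mix)
    unit_p = np.array([spec.unit_mix[u] for u in units])

    # with planted features the true pIC50 carries an additive fingerprint
    # signal (scaled to pic50_sd) plus Gaussian noise; otherwise it is drawn
    # from the population distribution directly
    mol_signal = None
    if spec.planted_features:
        from .descriptors import featurize

        lib = pd.DataFrame({"compound_id": [f"L{i}" for i in range(len(smiles))],
                            "smiles": smiles})
        fp = featurize(lib, family="substructure", mode="count", standardize=False)
        keys = list(fp.col_ids)
        raw = np.zeros(len(smiles))
        for key, w in spec.planted_features:
            raw = raw + float(w) * fp.values[:, keys.index(str(key))]
        mol_signal = (raw - raw.mean()) / raw.std() * spec.pic50_sd

    rows = []
    truth_rows = []
    for i in range(n):
        cid = f"SYN{i:05d}"
        smi = "" if rng.random() < spec.missing_smiles_rate else smiles[i % len(smiles)]
        if mol_signal is None:
            true_pic50 = spec.pic50_mean + rng.normal(0.0, spec.pic50_sd)
        else:
            true_pic50 = (spec.pic50_mean + mol_signal[i % len(smiles)]
                          + rng.normal(0.0, spec.noise_sd))
        n_rep = 1
        if rng.random() < spec.replicate_rate:
            n_rep += int(rng.integers(1, 3))
        noisy_group = n_rep > 1 and rng.random() < spec.noisy_replicate_rate
        clean_pic50s = []
        for rep in range(n_rep):
            if noisy_group:
                # alternate wide offsets so the replicate SD exceeds any
                # threshold near 2 log units
                jitter = (3.5 + rng.random()) * (1 if rep % 2 else -1)
            else:
                jitter = rng.normal(0.0, spec.replicate_jitter)
            pic50 = true_pic50 + jitter
            ic50_nM = from_pic50(pic50)
            qualifier = "="
            if rng.random() < spec.qualifier_rate:
                qualifier = "<" if rng.random() < 0.5 else ">"
            missing = rng.random() < spec.missing_rate
            unit = units[int(rng.choice(len(units), p=unit_p))]
            value = ic50_nM if unit == "nM" else ic50_nM / 1000.0
            rows.append(
                {
                    "compound_id": cid,
                    "smiles": smi,
                    "endpoint": "IC50",
                    "qualifier": qualifier,
                    "value": "" if missing else f"{value:.6g}",
                    "unit": unit,
                }
            )
            if qualifier == "=" and not missing and unit == "nM":
                clean_pic50s.append(pic50)
        # ground-truth verdict from the planted flags
        survives = bool(clean_pic50s) and bool(smi)
        if survives and len(clean_pic50s) > 1:
            survives = float(np.std(clean_pic50s, ddof=1)) < 2.0
        truth_rows.append(
            {
                "compound_id": cid,
                "smiles": smi,
                "true_pic50": true_pic50,
                "survives": survives,
                "expected_pic50": float(np.mean(clean_pic50s)) if survives else np.nan,
                "n_records": n_rep,
            }
        )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# planted responses


@dataclass(frozen=True)
class ResponseDecomposition:
    """Analytic variance split of a planted response."""

    signal_var: float
    noise_var: float
    q2_max: float  # var(signal) / (var(signal) + noise_var)
    realized_q2_max: float  # 1 - var(realized noise) / var(realized y)
    signal: np.ndarray
    weights: dict


def gen_response(X, planted_features, noise_sd: float, seed: int = 0, col_ids=None):
    """Additive planted signal: y = sum_k w_k X_k + Normal(0, noise_sd^2).

    ``planted_features`` is a sequence of (column key or index, weight).
    Returns ``(y, decomposition)`` with the analytic and realized noise
    ceilings, against which a learner's external Q2 can be judged.
    """
    X = np.asarray(X, dtype=float)
    keys = [str(c) for c in col_ids] if col_ids is not None else [str(j) for j in range(X.shape[1])]
    signal = np.zeros(X.shape[0])
    weights = {}
    for key, w in planted_features:
        k = str(key)
        if k not in keys:
            raise ValueError(f"planted feature {key!r} not among the matrix columns")
        signal = signal + float(w) * X[:, keys.index(k)]
        weights[k] = float(w)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=X.shape[0]) if noise_sd > 0 else np.zeros(X.shape[0])
    y = signal + eps
    sv = float(np.var(signal))
    nv = float(noise_sd**2)
    realized = 1.0 - float(np.var(eps)) / float(np.var(y)) if np.var(y) > 0 else np.nan
    return y, ResponseDecomposition(
        signal_var=sv,
        noise_var=nv,
        q2_max=sv / (sv + nv) if sv + nv > 0 else np.nan,
        realized_q2_max=realized,
        signal=signal,
        weights=weights,
    )


def noise_for_ceiling(signal, q2_max: float) -> float:
    """Noise SD that sets the analytic ceiling var(s)/(var(s)+sd^2) = q2_max."""
    if not 0.0 < q2_max < 1.0:
        raise ValueError("q2_max must be in (0, 1)")
    sv = float(np.var(np.asarray(signal, dtype=float)))
    return float(np.sqrt(sv * (1.0 - q2_max) / q2_max))


def gen_count_matrix(n: int, p: int, seed: int = 0, correlation: float = 0.0,
                     rate_low: float = 0.3, rate_high: float = 2.5):
    """Sparse count matrix emulating fingerprint-count columns.

    Columns are Poisson with rates drawn from [rate_low, rate_high]; a shared
    per-row lognormal size factor of strength ``correlation`` (>= 0) induces
    positive inter-column correlation, mimicking the molecular-size
    confounding of real count fingerprints.
    """
    rng = np.random.default_rng(seed)
    lam = rng.uniform(rate_low, rate_high, size=p)
    size = np.exp(rng.normal(0.0, correlation, size=n)) if correlation > 0 else np.ones(n)
    X = rng.poisson(size[:, None] * lam[None, :]).astype(float)
    cols = [f"F{j:03d}" for j in range(p)]
    return X, cols


# ---------------------------------------------------------------------------
# full-scale ChEMBL-like emulation

#: Composition plan realizing the canonical curation chain of a ChEMBL-20
#: acetylcholinesterase extract: survivor counts after each filter stage.
CHEMBL_PLAN = {
    "total_records": 9242,
    "total_compounds": 5049,
    "ic50_compounds": 4910,
    "after_qualifier": 3609,
    "after_unit": 3596,
    "after_sd": 2571,
    "final": 2570,
}

#: Default planted structure-activity drivers (catalog count keys, weights).
#: Secondary carbon leads, mirroring the feature set count fingerprints
#: typically surface as activity-relevant.
PLANTED_DEFAULT = (
    ("SubFPC2", 1.0),    # secondary carbon
    ("SubFPC1", 0.8),    # primary carbon
    ("SubFPC302", 0.6),  # rotatable bond
    ("SubFPC275", 0.5),  # heterocyclic
    ("SubFPC274", 0.4),  # aromatic atom
)

#: Emulated signal-to-noise: the planted ceiling Q2max of the curated set.
CHEMBL_CEILING = 0.80
#: pIC50 scale of the planted signal (log units) before noise.
SIGNAL_SD = 1.2


@dataclass
class ChemblEmulation:
    """A full-scale synthetic activity extract plus its ground truth."""

    records: pd.DataFrame
    survivor_ids: list[str]
    signal: pd.Series | None  # realized signal per surviving compound
    fingerprints: "object | None"  # DescriptorMatrix of survivors (count mode)
    plan: dict


def _survivor_pic50(rng, n_surv, smiles, planted, ceiling):
    """True pIC50 for the surviving compounds, planted on their fingerprints."""
    from .descriptors import featurize

    df = pd.DataFrame({"compound_id": [f"S{i}" for i in range(n_surv)], "smiles": smiles})
    fp = featurize(df, family="substructure", mode="count", standardize=False)
    raw = np.zeros(n_surv)
    keys = list(fp.col_ids)
    for key, w in planted:
        raw = raw + w * fp.values[:, keys.index(str(key))]
    scaled = (raw - raw.mean()) / raw.std() * SIGNAL_SD
    noise_sd = noise_for_ceiling(scaled, ceiling)
    pic50 = 6.0 + scaled + rng.normal(0.0, noise_sd, size=n_surv)
    return pic50, scaled + 6.0, fp


def gen_chembl_like_table(
    seed: int = 0,
    plan: dict | None = None,
    planted: tuple | None = PLANTED_DEFAULT,
    ceiling: float = CHEMBL_CEILING,
) -> ChemblEmulation:
    """Build a raw activity table realizing the canonical curation chain.

    The plan fixes how many compounds fall to each filter: non-IC50-only
    compounds, compounds whose IC50 records are all qualified or missing,
    all-micromolar compounds, replicate groups with pIC50 spread >= 2 log
    units, and one surviving compound without a SMILES.  Record totals are
    padded with concordant replicates.  With ``planted`` the survivors' pIC50
    carries the additive fingerprint signal at the configured noise ceiling;
    ``planted=None`` skips featurization (faster; counts only).
    """
    plan = dict(CHEMBL_PLAN if plan is None else plan)
    n_other = plan["total_compounds"] - plan["ic50_compounds"]
    n_qual = plan["ic50_compounds"] - plan["after_qualifier"]
    n_unit = plan["after_qualifier"] - plan["after_unit"]
    n_sd = plan["after_unit"] - plan["after_sd"]
    n_surv = plan["after_sd"]  # includes the no-SMILES compound
    n_final = plan["final"]
    if min(n_other, n_qual, n_unit, n_sd, n_surv - n_final) < 0 or n_final > n_surv:
        raise ValueError("inconsistent composition plan")
    base_records = n_other + n_qual + n_unit + 2 * n_sd + n_surv
    extras = plan["total_records"] - base_records
    if extras < 0:
        raise ValueError("total_records too small for the composition plan")

    rng = np.random.default_rng(seed)
    library = gen_molecules(n_final, seed=seed + 1)

    if planted:
        pic50_surv, signal, fp = _survivor_pic50(rng, n_final, library, planted, ceiling)
    else:
        pic50_surv = 6.0 + rng.normal(0.0, SIGNAL_SD / np.sqrt(CHEMBL_CEILING), size=n_final)
        signal, fp = None, None

    rows = []
    cid_counter = [0]

    def next_cid():
        cid_counter[0] += 1
        return f"CHEMBL-SYN{cid_counter[0]:05d}"

    def add(cid, smi, endpoint, qualifier, value, unit):
        rows.append({"compound_id": cid, "smiles": smi, "endpoint": endpoint,
                     "qualifier": qualifier, "value": value, "unit": unit})

    other_endpoints = ["Ki", "EC50", "% inhibition", "MIC"]
    for i in range(n_other):
        add(next_cid(), library[i % len(library)], other_endpoints[i % 4], "=",
            f"{rng.uniform(1, 1e4):.4g}", "nM")
    for i in range(n_qual):
        # all records qualified or missing: alternate the hazard kind
        cid = next_cid()
        smi = library[i % len(library)]
        if i % 3 == 2:
            add(cid, smi, "IC50", "=", "", "nM")  # missing value
        else:
            add(cid, smi, "IC50", "<" if i % 2 else ">", f"{rng.uniform(10, 1e5):.4g}", "nM")
    for i in range(n_unit):
        add(next_cid(), library[i % len(library)], "IC50", "=",
            f"{rng.uniform(0.01, 50):.4g}", "uM")
    for i in range(n_sd):
        # replicate pair 3.5-4.5 log units apart: pIC50 SD 2.5-3.2, over threshold
        cid = next_cid()
        smi = library[i % len(library)]
        center = 6.0 + rng.normal(0.0, 1.0)
        half = (3.5 + rng.random()) / 2.0
        add(cid, smi, "IC50", "=", f"{from_pic50(center - half):.6g}", "nM")
        add(cid, smi, "IC50", "=", f"{from_pic50(center + half):.6g}", "nM")

    # surviving compounds: concordant records, one compound without SMILES
    n_extra2 = extras // 2  # compounds receiving two extra replicates
    n_extra1 = extras - 2 * n_extra2  # and one compound with a single extra
    survivor_ids = []
    for i in range(n_surv):
        cid = next_cid()
        survivor_ids.append(cid)
        smi = "" if i == n_surv - 1 else library[i % n_final]
        n_rep = 1 + (2 if i < n_extra2 else (1 if i < n_extra2 + n_extra1 else 0))
        true = pic50_surv[i % n_final] if smi else 6.0
        for rep in range(n_rep):
            jitter = 0.0 if n_rep == 1 else float(rng.normal(0.0, 0.12))
            add(cid, smi, "IC50", "=", f"{from_pic50(true + jitter):.8g}", "nM")

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    assert len(records) == plan["total_records"]
    # shuffle record order so curation cannot rely on block structure
    records = records.sample(frac=1.0, random_state=seed % (2**32)).reset_index(drop=True)
    sig = None
    if signal is not None:
        sig = pd.Series(signal, index=survivor_ids[:n_final])
    if fp is not None:
        fp.row_ids = list(survivor_ids[:n_final])
    return ChemblEmulation(
        records=records,
        survivor_ids=survivor_ids[:n_final],
        signal=sig,
        fingerprints=fp,
        plan=plan,
    )
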