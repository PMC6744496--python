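import numpy as np
import pandas as pd
import pytest

from prdscan import experiments as ex
from prdscan import synthetic_data as sd
from prdscan import toxicity as tx
from prdscan import variant_table as vt
from prdscan.design import LibraryDesign, back_translate, tdp43_library


@pytest.fixture(scope="session")
def tiny_design() -> LibraryDesign:
    """Five-codon window for fast unit tests."""
    aa = "GNSRG"
    return LibraryDesign(
        wt_nt_seq=back_translate(aa),
        region_start=290,
        region_end=294,
        name="tiny",
    )


@pytest.fixture(scope="session")
def library_design() -> LibraryDesign:
    return tdp43_library("290-331")


@pytest.fixture(scope="session")
def landscape(library_design):
    return sd.make_landscape(library_design, seed=11)


@pytest.fixture(scope="session")
def simulated_run(library_design, landscape):
    """One moderate simulated experiment shared across test modules."""
    counts = sd.simulate_experiment(
        library_design, landscape, n_molecules=80_000, depth=1_000_000, seed=42
    )
    counts = vt.correct_misread_inflow(counts, library_design)
    records = vt.translate_and_aggregate(counts, library_design)
    filtered, log = vt.filter_variants(records)
    return {
        "counts": counts,
        "records": records,
        "filtered": filtered,
        "filter_log": log,
    }


@pytest.fixture(scope="session")
def toxicity_run(simulated_run, library_design):
    est, log = tx.estimate_toxicity(simulated_run["filtered"], library_design)
    est_raw, _ = tx.estimate_toxicity(
        simulated_run["filtered"], library_design, bayesian=False
    )
    merged = tx.merge_and_normalize([est])
    return {"estimates": est, "raw": est_raw, "merged": merged, "log": log}


@pytest.fixture(scope="session")
def calibration_result():
    """Full two-library estimator calibration against planted truth."""
    return ex.estimator_calibration(seed=1)


@pytest.fixture(scope="session")
def structure_recovery_result():
    """End-to-end planted helix/strand recovery."""
    return ex.structure_recovery(seed=2)


def make_count_records(
    design: LibraryDesign,
    toxicities: np.ndarray,
    lam_in: np.ndarray,
    seed: int,
    *,
    replicate_noise_sd: float = 0.0,
    n_silent: int = 30,
    lam_wt: float = 2e5,
    n_doubles: int = 0,
    lam_double: float = 1e4,
    double_noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Synthetic aggregated record table with known per-variant toxicity.

    Builds Poisson counts directly at the record level (bypassing the
    nucleotide simulation) for estimator-focused tests: one WT row, a
    block of silent rows (toxicity 0) and one row per entry of
    ``toxicities`` (singles at arbitrary positions). Output counts follow
    the exponential-competition expectation with the design's
    generations.
    """
    rng = np.random.default_rng(seed)
    n_var = len(toxicities)
    rows = []
    wt_aa = design.wt_aa_seq

    def row(mut, n_aa, silent, wt):
        return {
            "aa_seq": wt_aa,
            "mutations": mut,
            "n_aa_mut": n_aa,
            "n_codon_mut": 1 if (silent or n_aa) else 0,
            "is_wt": wt,
            "is_silent": silent,
            "is_stop": False,
            "has_extra_syn": False,
        }

    rows.append(row((), 0, False, True))
    for _ in range(n_silent):
        rows.append(row((), 0, True, False))
    positions = list(design.positions)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    single_muts = []
    for i in range(n_var):
        pos = positions[i % len(positions)]
        wt = design.wt_aa(pos)
        alternatives = [a for a in aas if a != wt]
        mut = alternatives[(i // len(positions)) % len(alternatives)]
        single_muts.append((pos, wt, mut))
        rows.append(row((single_muts[-1],), 1, False, False))

    double_tox = []
    if n_doubles:
        for _ in range(n_doubles):
            while True:
                i, j = rng.choice(n_var, size=2, replace=False)
                if single_muts[i][0] != single_muts[j][0]:
                    break
            m1, m2 = sorted((single_muts[i], single_muts[j]))
            rows.append(row((m1, m2), 2, False, False))
            double_tox.append(
                toxicities[i] + toxicities[j]
                + rng.normal(0.0, double_noise_sd)
            )
    df = pd.DataFrame(rows)

    tox = np.concatenate(
        [[0.0], np.zeros(n_silent), np.asarray(toxicities), double_tox]
    )
    lam = np.concatenate(
        [[lam_wt], np.full(n_silent, np.median(lam_in)), np.asarray(lam_in),
         np.full(n_doubles, lam_double)]
    )
    for r in range(1, design.n_replicates + 1):
        G = design.generations[r - 1]
        df[f"input{r}"] = rng.poisson(lam)
        eta = rng.normal(0.0, replicate_noise_sd, size=len(tox))
        eta[0] = 0.0
        w = lam * np.exp(-(tox + eta) * G)
        scale = lam.sum() / w.sum()
        for o in "ab"[: design.n_output_per_replicate]:
            df[f"output{r}{o}"] = rng.poisson(w * scale / 2)
    return df
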