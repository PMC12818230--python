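"""Generator invariants: determinism, prevalence, lead identities,
missing-at-random labs, and registry/annotation consistency."""

import numpy as np
import pytest
from scipy import stats

from omipipe import (
    CohortConfig,
    EcgMorphParams,
    InputError,
    PatientCase,
    RegistryOutcome,
    annotate_omi,
    apply_missingness,
    derive_limb_leads,
    generate_cohort,
    load_cohort,
    save_cohort,
    synthesize_ecg,
)
from omipipe.types import EIGHT_LEADS, TWELVE_LEADS


def _case_signature(case):
    return (
        case.patient_id,
        case.age,
        case.sex,
        tuple(sorted(case.history_flags.items())),
        case.hs_ctnt_initial_ng_l,
        tuple(e.samples.tobytes() for e in case.ecgs),
        tuple(sorted(vars(case.registry).items(), key=lambda kv: kv[0])),
    )


def test_same_seed_gives_identical_cohorts():
    config = CohortConfig(n_patients=40, sampling_rate_hz=100.0, seed=5)
    a = generate_cohort(config)
    b = generate_cohort(CohortConfig(n_patients=40, sampling_rate_hz=100.0, seed=5))
    assert [_case_signature(c) for c in a] == [_case_signature(c) for c in b]


def test_omi_count_within_binomial_interval(small_cohort):
    config, cases = small_cohort
    n_omi = sum(c.latent_truth == "OMI" for c in cases)
    lo = stats.binom.ppf(0.005, config.n_patients, config.omi_prevalence)
    hi = stats.binom.ppf(0.995, config.n_patients, config.omi_prevalence)
    assert lo <= n_omi <= hi


def test_zero_prevalence_cohort_has_no_occlusions():
    config = CohortConfig(
        n_patients=60, omi_prevalence=0.0, sampling_rate_hz=100.0, seed=3
    )
    cases = generate_cohort(config)
    assert all(c.latent_truth != "OMI" for c in cases)
    for c in cases:
        assert not c.registry.scaar_aco
        if c.registry.timi_flow in (0, 1):
            assert not c.registry.culprit_lesion


def test_invalid_fractions_rejected():
    with pytest.raises(InputError):
        CohortConfig(n_patients=10, omi_prevalence=1.5).validate()
    with pytest.raises(InputError):
        CohortConfig(n_patients=10, omi_prevalence=0.6, nomi_prevalence=0.5).validate()


# -- lead derivation --------------------------------------------------------

def test_limb_lead_arithmetic_on_constant_signals():
    x = np.zeros((8, 10))
    x[EIGHT_LEADS.index("I")] = 0.2
    x[EIGHT_LEADS.index("II")] = 0.5
    twelve, names = derive_limb_leads(x, EIGHT_LEADS)
    lead = dict(zip(names, twelve))
    assert np.allclose(lead["III"], 0.3)
    assert np.allclose(lead["aVR"], -0.35)
    assert np.allclose(lead["aVL"], -0.05)
    assert np.allclose(lead["aVF"], 0.4)
    zero, _ = derive_limb_leads(np.zeros((8, 5)), EIGHT_LEADS)
    assert np.all(zero == 0)


def test_limb_lead_derivation_is_idempotent():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(8, 200))
    twelve, names = derive_limb_leads(x, EIGHT_LEADS)
    again, _ = derive_limb_leads(
        np.stack([twelve[names.index(l)] for l in EIGHT_LEADS]), EIGHT_LEADS
    )
    assert np.allclose(twelve, again, atol=0)


def test_missing_lead_rejected():
    with pytest.raises(InputError):
        derive_limb_leads(np.zeros((7, 5)), EIGHT_LEADS[:-1])


def test_every_emitted_ecg_satisfies_lead_identities(small_cohort):
    _, cases = small_cohort
    checked = 0
    for case in cases[:80]:
        for ecg in case.ecgs:
            i, ii = ecg.lead("I"), ecg.lead("II")
            assert np.allclose(ecg.lead("III"), ii - i, atol=1e-9)
            assert np.allclose(ecg.lead("aVR"), -(i + ii) / 2, atol=1e-9)
            assert np.allclose(ecg.lead("aVL"), i - ii / 2, atol=1e-9)
            assert np.allclose(ecg.lead("aVF"), ii - i / 2, atol=1e-9)
            checked += 1
    assert checked > 50


# -- missingness ------------------------------------------------------------

def _bare_cases(n, seed):
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        latent = "OMI" if rng.random() < 0.02 else "NO_AMI"
        cases.append(
            PatientCase(
                patient_id=f"B{i}",
                age=60.0,
                sex="male",
                poc_labs={"hemoglobin": 140.0, "creatinine": 80.0, "glucose": 6.0},
                hs_ctnt_initial_ng_l=10.0,
                ecgs=[],
                latent_truth=latent,
            )
        )
    return cases


def test_zero_rate_masks_nothing():
    cases = _bare_cases(200, 0)
    apply_missingness(cases, {"glucose": 0.0}, seed=1)
    assert all(c.poc_labs["glucose"] is not None for c in cases)


def test_observed_missingness_rate_matches_binomial():
    n = 10_000
    cases = _bare_cases(n, 1)
    apply_missingness(cases, {"glucose": 0.05}, seed=2)
    k = sum(c.poc_labs["glucose"] is None for c in cases)
    assert stats.binom.ppf(0.005, n, 0.05) <= k <= stats.binom.ppf(0.995, n, 0.05)


def test_missingness_independent_of_outcome():
    n = 10_000
    cases = _bare_cases(n, 2)
    apply_missingness(cases, {"glucose": 0.05}, seed=3)
    miss = np.array([c.poc_labs["glucose"] is None for c in cases], dtype=float)
    omi = np.array([c.latent_truth == "OMI" for c in cases], dtype=float)
    r = np.corrcoef(miss, omi)[0, 1]
    assert abs(r) < 0.03


# -- registry consistency ---------------------------------------------------

def test_registry_consistent_with_annotation_branches(small_cohort):
    _, cases = small_cohort
    for case in cases:
        label = annotate_omi(case.registry)
        if case.latent_truth == "OMI":
            assert label.status == "OMI", case.latent_branch
        elif case.latent_truth == "NO_AMI":
            assert label.status == "NO_AMI"
        else:
            assert label.status in ("NOMI", "NEEDS_REVIEW", "EXCLUDED") or (
                label.status == "NOMI"
            )


def test_subtle_omi_sits_below_stemi_threshold(small_cohort):
    # subtle/occult cases carry no above-threshold ST offset by construction
    config, cases = small_cohort
    n_subtle = sum(
        1
        for c in cases
        if c.latent_truth == "OMI"
        and c.latent_branch
        and c.latent_branch.endswith("subtle")
    )
    n_omi = sum(c.latent_truth == "OMI" for c in cases)
    assert 0 < n_subtle < n_omi


def test_extra_ecgs_recorded_after_index(small_cohort):
    _, cases = small_cohort
    for case in cases:
        if len(case.ecgs) > 1:
            assert case.ecgs[0].recorded_at < case.ecgs[1].recorded_at


# -- waveform params --------------------------------------------------------

def test_morph_param_validation():
    with pytest.raises(InputError):
        EcgMorphParams(heart_rate=250.0)
    with pytest.raises(InputError):
        EcgMorphParams(wave_params={"R": (1.0, 0.0, -0.01)})
    with pytest.raises(InputError):
        EcgMorphParams(st_offset_mv={"III": 0.1})  # derived lead, not settable


def test_lvh_scales_r_and_lbbb_widens_qrs(make_ecg):
    normal = make_ecg(sampling_rate_hz=100.0)
    lvh = make_ecg(morphology="LVH", sampling_rate_hz=100.0)
    lbbb = make_ecg(morphology="LBBB", sampling_rate_hz=100.0)
    assert lvh.lead("II").max() > 1.5 * normal.lead("II").max()
    # widened QRS: more samples with large slope around R
    def qrs_width(sig):
        d = np.abs(np.diff(sig.lead("II")))
        return np.sum(d > 0.1)
    assert qrs_width(lbbb) > qrs_width(normal)
    assert lbbb.morphology_flags == frozenset({"LBBB"})


def test_cohort_roundtrip_through_disk(tmp_path, small_cohort):
    _, cases = small_cohort
    subset = cases[:25]
    save_cohort(subset, tmp_path)
    loaded = load_cohort(tmp_path)
    assert len(loaded) == len(subset)
    for a, b in zip(subset, loaded):
        assert a.patient_id == b.patient_id
        assert a.latent_truth == b.latent_truth
        assert a.sex == b.sex
        assert len(a.ecgs) == len(b.ecgs)
        for key, value in vars(a.registry).items():
            loaded_value = getattr(b.registry, key)
            if isinstance(value, float):
                assert loaded_value == pytest.approx(value)
            else:
                assert loaded_value == value
        if a.ecgs:
            assert np.allclose(
                a.ecgs[0].samples, b.ecgs[0].samples, atol=1e-4
            )  # stored as float32
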