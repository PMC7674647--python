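import logging

import pytest

from alarmone.synthetic import (
    LigandSpec,
    SiteSpec,
    build_nucleotide,
    build_site,
)

logging.getLogger("alarmone").setLevel(logging.ERROR)

#: published conformer torsions (nu0..nu4, chi) with the frozen expected
#: pseudorotation outputs (P, nu_max, pucker class, syn/anti)
REPORTED_CONFORMERS = {
    "ppGpp_unbound": dict(nu=(-6.88, 26.92, -35.87, 33.24, -16.53), chi=-99.58,
                          P=188.23, nu_max=36.24, pucker="C3'-exo", glyc="anti"),
    "pppGpp_unbound": dict(nu=(-7.88, 26.79, -34.64, 31.48, -14.82), chi=84.22,
                           P=186.23, nu_max=34.85, pucker="C3'-exo", glyc="syn"),
    "6EX0": dict(nu=(-8.46, -13.71, 31.52, -37.17, 27.46), chi=171.65,
                 P=31.47, nu_max=36.96, pucker="C3'-endo", glyc="anti"),
    "5VSW": dict(nu=(-13.05, 25.53, -27.83, 19.75, -4.28), chi=-116.08,
                 P=170.36, nu_max=28.23, pucker="C2'-endo", glyc="anti"),
    "6G14": dict(nu=(-22.30, 33.40, -32.51, 18.75, 2.27), chi=-112.79,
                 P=158.59, nu_max=34.92, pucker="C2'-endo", glyc="anti"),
    "6GFM": dict(nu=(-32.38, 44.35, -38.72, 19.11, 8.42), chi=65.89,
                 P=151.01, nu_max=44.27, pucker="C2'-endo", glyc="syn"),
}


@pytest.fixture(scope="session")
def ppgpp():
    ligand, pdb_text = build_nucleotide(LigandSpec())
    return ligand


@pytest.fixture(scope="session")
def pppgpp():
    ligand, _ = build_nucleotide(LigandSpec(include_gamma_phosphate=True))
    return ligand


@pytest.fixture(scope="session")
def syn_ppgpp():
    row = REPORTED_CONFORMERS["6GFM"]
    ligand, _ = build_nucleotide(LigandSpec(
        P_target=row["P"], nu_max_target=row["nu_max"], chi_target=row["chi"],
        gamma_target=-143.14))
    return ligand


@pytest.fixture(scope="session")
def nine_category_complex(ppgpp):
    spec = SiteSpec(seed=11)
    model = build_site(ppgpp, spec, pdb_id="NINE0")
    return model, ppgpp, spec
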