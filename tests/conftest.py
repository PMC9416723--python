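import pytest

from pyrethroid_hbm import load_default_exposure, load_registry
from pyrethroid_hbm.tiers import run_tier_i, tier_i_guidance


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def exposure():
    return load_default_exposure()


@pytest.fixture(scope="session")
def tier_i_results(registry, exposure):
    results = []
    for population in ("children", "adults"):
        rows = [s for s in exposure if s.population_id == population]
        results += run_tier_i(rows, tier_i_guidance(registry, population))
    return results


# Published substance-specific RCR matrix: (study, population, biomarker,
# substance, printed value as a string — the string length encodes the
# printed precision).  "NR" marks percentiles that could not be estimated.
TABLE5_CELLS = [
    ("IL-RAVMABAT", "children", "ClF3CA", "lambda-cyhalothrin", "0.085"),
    ("IL-RAVMABAT", "children", "ClF3CA", "bifenthrin", "0.013"),
    ("IL-RAVMABAT", "children", "DBCA", "deltamethrin", "0.011"),
    ("IL-RAVMABAT", "children", "DCCA", "cypermethrin", "0.17"),
    ("IL-RAVMABAT", "children", "DCCA", "permethrin", "0.016"),
    ("IL-RAVMABAT", "children", "4-FPBA", "cyfluthrin", "0.013"),
    ("NL-SPECIMEN", "children", "ClF3CA", "lambda-cyhalothrin", "0.142"),
    ("NL-SPECIMEN", "children", "ClF3CA", "bifenthrin", "0.021"),
    ("NL-SPECIMEN", "children", "DBCA", "deltamethrin", "0.042"),
    ("NL-SPECIMEN", "children", "DCCA", "cypermethrin", "0.15"),
    ("NL-SPECIMEN", "children", "DCCA", "permethrin", "0.014"),
    ("NL-SPECIMEN", "children", "4-FPBA", "cyfluthrin", "NR"),
    ("BE-3xG", "children", "ClF3CA", "lambda-cyhalothrin", "0.086"),
    ("BE-3xG", "children", "ClF3CA", "bifenthrin", "0.013"),
    ("BE-3xG", "children", "DBCA", "deltamethrin", "0.034"),
    ("BE-3xG", "children", "DCCA", "cypermethrin", "0.25"),
    ("BE-3xG", "children", "DCCA", "permethrin", "0.02"),
    ("BE-3xG", "children", "4-FPBA", "cyfluthrin", "NR"),
    ("CY-ORGANIKO", "children", "ClF3CA", "lambda-cyhalothrin", "0.029"),
    ("CY-ORGANIKO", "children", "ClF3CA", "bifenthrin", "0.004"),
    ("CY-ORGANIKO", "children", "DBCA", "deltamethrin", "0.044"),
    ("CY-ORGANIKO", "children", "DCCA", "cypermethrin", "0.20"),
    ("CY-ORGANIKO", "children", "DCCA", "permethrin", "0.02"),
    ("CY-ORGANIKO", "children", "4-FPBA", "cyfluthrin", "NR"),
    ("FR-ESTEBAN", "children", "DBCA", "deltamethrin", "0.059"),
    ("FR-ESTEBAN", "children", "DCCA", "cypermethrin", "0.108"),
    ("FR-ESTEBAN", "children", "DCCA", "permethrin", "0.01"),
    ("FR-ESTEBAN", "children", "4-FPBA", "cyfluthrin", "0.004"),
    ("SI-SLOCRP", "children", "ClF3CA", "lambda-cyhalothrin", "NR"),
    ("SI-SLOCRP", "children", "DBCA", "deltamethrin", "NR"),
    ("SI-SLOCRP", "children", "DCCA", "cypermethrin", "NR"),
    ("SI-SLOCRP", "children", "4-FPBA", "cyfluthrin", "0.018"),
    ("CH-HBM4EU", "adults", "ClF3CA", "lambda-cyhalothrin", "0.031"),
    ("CH-HBM4EU", "adults", "ClF3CA", "bifenthrin", "0.005"),
    ("CH-HBM4EU", "adults", "DBCA", "deltamethrin", "0.0068"),
    ("CH-HBM4EU", "adults", "DCCA", "cypermethrin", "0.036"),
    ("CH-HBM4EU", "adults", "DCCA", "permethrin", "0.003"),
    ("CH-HBM4EU", "adults", "4-FPBA", "cyfluthrin", "NR"),
    ("DE-ESB", "adults", "ClF3CA", "lambda-cyhalothrin", "0.019"),
    ("DE-ESB", "adults", "ClF3CA", "bifenthrin", "0.003"),
    ("DE-ESB", "adults", "DBCA", "deltamethrin", "0.0041"),
    ("DE-ESB", "adults", "DCCA", "cypermethrin", "0.019"),
    ("DE-ESB", "adults", "4-FPBA", "cyfluthrin", "NR"),
    ("IL-RAVMABAT", "adults", "ClF3CA", "lambda-cyhalothrin", "0.075"),
    ("IL-RAVMABAT", "adults", "ClF3CA", "bifenthrin", "0.012"),
    ("IL-RAVMABAT", "adults", "DBCA", "deltamethrin", "0.0032"),
    ("IL-RAVMABAT", "adults", "DCCA", "cypermethrin", "0.068"),
    ("IL-RAVMABAT", "adults", "DCCA", "permethrin", "0.006"),
    ("IL-RAVMABAT", "adults", "4-FPBA", "cyfluthrin", "NR"),
    ("FR-ESTEBAN", "adults", "DBCA", "deltamethrin", "0.041"),
    ("FR-ESTEBAN", "adults", "DCCA", "cypermethrin", "0.053"),
    ("FR-ESTEBAN", "adults", "DCCA", "permethrin", "0.005"),
    ("FR-ESTEBAN", "adults", "4-FPBA", "cyfluthrin", "0.003"),
]


def printed_decimals(text: str) -> int:
    return len(text.split(".")[1])
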