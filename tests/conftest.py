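import pytest

from certcoder.certificates import (
    AuxiliaryVariables,
    CertificateCodes,
    CertificateText,
    DeathCertificate,
)
from certcoder.icd10 import parse_code
from certcoder.synthetic import build_grammar

AUX = AuxiliaryVariables(gender=2, year=2013, age_class="80-84", origin="paper")

# the classic worked certificate: stroke chain with a fall, coded per line
CHAIN_LINES = (
    "Stroke in September left hemiparesis",
    "Fall scalp laceration fracture humerus",
    "Coronary artery disease",
    "Acute intracranial hemorrhage",
    "",
    "Dementia depression hypertension",
)
CHAIN_CODES_ALIGNED = (
    ("I64", "G819"),
    ("S010", "W19", "S423"),
    ("I251",),
    ("I629",),
    (),
    ("F03", "F329", "I10"),
)
# database-style misalignment: line 4's code stored at the front of line 3
CHAIN_CODES_MISALIGNED = (
    ("I64", "G819"),
    ("S010", "W19", "S423"),
    ("I629", "I251"),
    (),
    (),
    ("F03", "F329", "I10"),
)
# flat target in backward order (part 2 first), identical for both layouts
CHAIN_FLAT_TARGET = ["F03", "F329", "I10", "I629", "I251", "S010", "W19", "S423", "I64", "G819"]


def make_cert(lines, per_line_codes, cert_id="t1", aux=AUX):
    codes = CertificateCodes(
        tuple(tuple(parse_code(c) for c in seq) for seq in per_line_codes)
    )
    return DeathCertificate(
        id=cert_id, text=CertificateText(tuple(lines)), aux=aux, codes=codes
    )


@pytest.fixture
def chain_cert_aligned():
    return make_cert(CHAIN_LINES, CHAIN_CODES_ALIGNED)


@pytest.fixture
def chain_cert_misaligned():
    # text is unchanged: misalignment is purely a code-storage artifact
    return make_cert(CHAIN_LINES, CHAIN_CODES_MISALIGNED)


@pytest.fixture(scope="session")
def grammar():
    return build_grammar(160, 120, seed=7)
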