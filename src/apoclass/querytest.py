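"""Embedded query-test fixture: 51 insect transcriptomes versus the
hexapod code database.

Each row carries the species, the printed identification result (the name
of the clade the query was assigned to), the *generated* barcode observed
from the transcriptome (may contain X = missing residue, ? = missing
gene), the *designed* barcode of the true terminal category in the
database, and the printed category.  Strings are stored exactly as
printed, including the label "Coleopterodea" and one anomalous ID token
("X_A_" in the Thaumetopoea row) that the barcode parser normalizes.

The designed barcodes jointly define the code trie of the classification
system between superclass and order level; internal-clade display names
known from the published description (Insecta, Pterygota, Holometabola,
Polyneoptera, ...) are included so assignments that stop above order level
can be reported by name.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coding import Barcode, CodeDatabase, parse_barcode
from .identify import QueryObservation, observation_from_barcode

#: display names for internal (supra-ordinal) clades, keyed by code ID
CLADE_NAMES = {
    "00": "Hexapoda",
    "02": "Insecta",
    "03": "Ectognatha",
    "08": "Pterygota",
    "0D": "Polyneoptera",
    "0X": "Holometabola",
    "16": "Coleopterodea",
}

# (species, printed result, generated barcode, designed barcode, printed category)
_ROWS = (
    ("Pantala flavescens fabricius", "Pterygota",
     "T_00_I_02_X_03_E_06_R_08_X_09_X_0B_",
     "T_00_I_02_G_03_E_06_R_08_S_09_C_0B_", "False-negative"),
    ("Ischnura elegans", "Odonata",
     "X_00_I_02_X_03_E_06_R_08_X_09_C_0B_",
     "T_00_I_02_G_03_E_06_R_08_S_09_C_0B_", "Positive"),
    ("Isonychia kiangsinensis", "Ephemeroptera",
     "T_00_I_02_X_03_X_06_R_08_X_09_Q_0A_",
     "T_00_I_02_G_03_E_06_R_08_S_09_Q_0A_", "Positive"),
    ("Ephemera sp.", "Ephemeroptera",
     "T_00_I_02_X_03_E_06_R_08_S_09_Q_0A_",
     "T_00_I_02_G_03_E_06_R_08_S_09_Q_0A_", "Positive"),
    ("Eparchus insignis", "Dermaptera",
     "X_00_I_02_?_03_E_06_R_08_X_0C_Q_0D_H_0E_F_0F_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_H_0E_F_0F_", "Positive"),
    ("Flavoperla sp.", "Plecoptera",
     "X_00_I_02_X_03_?_06_R_08_X_0C_Q_0D_S_0G_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_S_0G_", "Positive"),
    ("Chondracris rosea", "Orthoptera",
     "T_00_I_02_X_03_E_06_R_08_S_0C_Q_0D_M_0H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_M_0H_", "Positive"),
    ("Gryllotalpa unispina", "Orthoptera",
     "?_00_I_02_X_03_E_06_R_08_S_0C_Q_0D_M_0H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_M_0H_", "Positive"),
    ("Hymenopus coronatus", "Mantodea",
     "X_00_I_02_X_03_E_06_R_08_S_0C_Q_0D_M_0I_H_0P_C_0R_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_M_0I_H_0P_C_0R_", "Positive"),
    ("Phraortes sp.", "Phasmida",
     "T_00_I_02_X_03_X_06_R_08_X_0C_Q_0D_M_0I_X_0J_L_0M_V_0O_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_M_0I_K_0J_L_0M_V_0O_", "Positive"),
    ("Coptotermes formosanus", "Blattodea",
     "T_00_I_02_X_03_E_06_R_08_S_0C_Q_0D_M_0I_H_0P_T_0S_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_M_0I_H_0P_T_0S_", "Positive"),
    ("Eupolyphaga sinensis", "Blattodea",
     "T_00_I_02_X_03_E_06_R_08_S_0C_Q_0D_M_0I_X_0P_T_0S_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_M_0I_H_0P_T_0S_", "Positive"),
    ("Periplaneta Americana", "Blattodea",
     "T_00_I_02_X_03_E_06_R_08_X_0C_Q_0D_M_0I_X_0P_T_0S_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_Q_0D_M_0I_H_0P_T_0S_", "Positive"),
    ("Pedetontus sp.", "Archaeognatha",
     "T_00_I_02_X_03_N_05_",
     "T_00_I_02_G_03_N_05_", "Positive"),
    ("Lepisma sp.", "Zygentoma",
     "T_00_I_02_X_03_E_06_T_07_",
     "T_00_I_02_G_03_E_06_T_07_", "Positive"),
    ("Anoplophora glabripennis", "Coleopterodea",
     "T_00_I_02_X_03_?_06_R_08_S_0C_X_0V_N_0X_N_0Z_R_10_H_16_X_18_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_",
     "False negative"),
    ("Antheraea assama", "Lepidoptera",
     "T_00_I_02_G_03_X_06_R_08_S_0C_X_0V_N_0X_N_0Z_N_19_L_1A_E_1C_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_L_1A_E_1C_", "Positive"),
    ("Anthonomus grandis", "Coleoptera",
     "?_00_I_02_X_03_E_06_R_08_X_0C_X_0V_N_0X_X_0Z_R_10_H_16_K_18_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_", "Positive"),
    ("Bactrocera dorsalis", "Diptera",
     "?_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_", "Positive"),
    ("Belgica antarctica", "Diptera",
     "T_00_I_02_?_03_E_06_R_08_S_0C_I_0V_?_0X_N_0Z_N_19_A_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_", "Positive"),
    ("Brassicogethes aeneus", "Coleoptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_X_0V_N_0X_N_0Z_R_10_X_16_K_18_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_", "Positive"),
    ("Chrysopa pallens", "Neuroptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_X_0V_N_0X_N_0Z_R_10_M_11_X_13_C_15_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_M_11_M_13_C_15_",
     "Positive"),
    ("Colaphellus bowringi", "Coleoptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_", "Positive"),
    ("Corydalinae sp.", "Megaloptera",
     "T_00_I_02_X_03_?_06_R_08_X_0C_X_0V_X_0X_N_0Z_R_10_X_11_X_13_R_14_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_M_11_M_13_R_14_",
     "Positive"),
    ("Crioscolia alcione", "Hymenoptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_X_0V_N_0X_L_0Y_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_L_0Y_", "Positive"),
    ("Culicoides sp.", "Diptera",
     "T_00_I_02_G_03_E_06_R_08_?_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_", "Positive"),
    ("Dastarcus helophoroides", "Coleoptera",
     "T_00_I_02_X_03_E_06_R_08_S_0C_X_0V_N_0X_N_0Z_R_10_H_16_K_18_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_", "Positive"),
    ("Delia antiqua", "Diptera",
     "T_00_I_02_?_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_", "Positive"),
    ("Fopius arisanus", "Hymenoptera",
     "T_00_X_02_G_03_E_06_?_08_X_0C_I_0V_N_0X_L_0Y_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_L_0Y_", "Positive"),
    ("Hypothenemus hampei", "Coleoptera",
     "T_00_I_02_?_03_E_06_?_08_?_0C_?_0V_N_0X_?_0Z_R_10_H_16_K_18_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_", "Positive"),
    ("Ips typographus", "Coleoptera",
     "T_00_X_02_?_03_?_06_R_08_?_0C_X_0V_?_0X_X_0Z_R_10_X_16_K_18_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_", "Positive"),
    ("Lymantria dispar", "Lepidoptera",
     "T_00_I_02_?_03_X_06_R_08_X_0C_X_0V_N_0X_X_0Z_N_19_L_1A_E_1C_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_L_1A_E_1C_", "Positive"),
    ("Musca domestica", "Diptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_X_0V_X_0X_N_0Z_N_19_A_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_", "Positive"),
    ("Nevrorthus apatelios", "Neuroptera",
     "?_00_?_02_?_03_X_06_?_08_?_0C_X_0V_?_0X_?_0Z_R_10_?_11_X_13_C_15_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_M_11_M_13_C_15_",
     "Positive"),
    ("Nicrophorus vespilloides", "Coleoptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_H_16_K_18_",
     "Positive *"),
    ("Oropsylla silantiewi", "Siphonaptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_G_1E_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_G_1E_",
     "Positive *"),
    ("Osmia cornuta", "Hymenoptera",
     "T_00_I_02_G_03_E_06_R_08_X_0C_X_0V_N_0X_L_0Y_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_L_0Y_", "Positive"),
    ("Polistes metricus", "Hymenoptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_X_0X_L_0Y_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_L_0Y_", "Positive"),
    ("Raphidia ariadne", "Raphidioptera",
     "T_00_X_02_G_03_?_06_R_08_X_0C_X_0V_?_0X_X_0Z_?_10_X_11_N_12_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_R_10_M_11_N_12_",
     "Positive"),
    ("Rhodinia newara", "Lepidoptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_X_0V_N_0X_N_0Z_N_19_L_1A_E_1C_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_L_1A_E_1C_", "Positive"),
    ("Samia ricini", "Lepidoptera",
     "T_00_I_02_G_03_X_06_R_08_S_0C_X_0V_N_0X_X_0Z_N_19_L_1A_E_1C_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_L_1A_E_1C_", "Positive"),
    ("Sitodiplosis mosellana", "Diptera",
     "?_00_I_02_G_03_?_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_?_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_", "Positive"),
    ("Stomoxys calcitrans", "Diptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "Positive *"),
    ("Telchin licus", "Lepidoptera",
     "?_00_?_02_G_03_X_06_R_08_X_0C_X_0V_?_0X_?_0Z_N_19_?_1A_E_1C_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_L_1A_E_1C_", "Positive"),
    ("Telenomus podisi", "Hymenoptera",
     "T_00_X_02_?_03_E_06_R_08_S_0C_X_0V_N_0X_L_0Y_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_L_0Y_", "Positive"),
    ("Teleopsis whitei", "Diptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "Positive *"),
    ("Tetramorium bicarinatum", "Hymenoptera",
     "T_00_I_02_?_03_E_06_R_08_S_0C_X_0V_N_0X_L_0Y_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_L_0Y_", "Positive"),
    ("Thaumetopoea pityocampa", "Lepidoptera",
     "?_00_?_02_?_03_?_06_R_08_?_0C_?_0V_X_0X_?_0Z_N_19_X_A_E_1C_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_L_1A_E_1C_", "Positive"),
    ("Themira biloba", "Diptera",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_A_1D_Y_1H_",
     "Positive *"),
    ("Xyela alpigena", "Holometabola",
     "?_00_?_02_?_03_X_06_X_08_?_0C_X_0V_N_0X_?_0Y_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_L_0Y_", "False-negative"),
    ("Yponomeuta evonymellus", "Lepidoptera",
     "X_00_I_02_X_03_X_06_R_08_S_0C_X_0V_N_0X_X_0Z_N_19_L_1A_E_1C_",
     "T_00_I_02_G_03_E_06_R_08_S_0C_I_0V_N_0X_N_0Z_N_19_L_1A_E_1C_", "Positive"),
)


@dataclass(frozen=True)
class FixtureRow:
    species: str
    result: str                 # printed assigned-clade name
    generated: str              # observed barcode string, verbatim
    designed: str               # database barcode string, verbatim
    printed_category: str       # verbatim category cell
    category: str               # normalized: positive | false_negative
    complete_match_star: bool   # printed "*" complete-match marker

    @property
    def generated_barcode(self) -> Barcode:
        return parse_barcode(self.generated, kind="generated")

    @property
    def designed_barcode(self) -> Barcode:
        return parse_barcode(self.designed)

    @property
    def truth_terminal_id(self) -> str:
        return self.designed_barcode.ids[-1]


def _normalize_category(printed: str) -> tuple[str, bool]:
    base = printed.replace("*", "").strip()
    star = "*" in printed
    key = base.lower().replace("-", " ").replace("  ", " ").strip()
    mapping = {
        "positive": "positive",
        "false negative": "false_negative",
        "false positive": "false_positive",
        "negative": "negative",
    }
    return mapping[key], star


def query_test_fixture() -> list[FixtureRow]:
    """The 51 fixture rows, verbatim strings plus normalized categories."""
    rows = []
    for species, result, generated, designed, printed in _ROWS:
        category, star = _normalize_category(printed)
        rows.append(
            FixtureRow(species, result, generated, designed, printed,
                       category, star)
        )
    return rows


def query_test_database(rows: list[FixtureRow] | None = None) -> CodeDatabase:
    """Code database (trie of designed barcodes) underlying the fixture.

    Terminal categories are named by the order-level Result labels of the
    positively identified rows; internal clades carry the published names.
    """
    rows = rows if rows is not None else query_test_fixture()
    terminal_names: dict[str, str] = {}
    for row in rows:
        if row.category == "positive":
            terminal_names.setdefault(row.truth_terminal_id, row.result)
    barcodes = {}
    for row in rows:
        name = terminal_names[row.truth_terminal_id]
        barcodes.setdefault(name, row.designed)
    return CodeDatabase.from_designed_barcodes(barcodes, CLADE_NAMES)


def fixture_queries(
    rows: list[FixtureRow] | None = None,
) -> list[tuple[str, QueryObservation, str]]:
    """(species, observation, truth-terminal key) triples for evaluation."""
    rows = rows if rows is not None else query_test_fixture()
    return [
        (row.species, observation_from_barcode(row.generated),
         row.truth_terminal_id)
        for row in rows
    ]
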