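"""Shared fixtures: the worked rubric example sentences and small corpora."""

from __future__ import annotations

import pytest

from ndchealth.corpus_io import Document, PreprocessConfig, tokenize
from ndchealth.health_scoring import HealthLexicon

# Excerpts from publicly available NDC submissions (UNFCCC registry), used as
# worked examples for the classification rubric: (doc_id, text, expected
# (group, level), expected entry score).
NDC_SNIPPETS: list[tuple[str, str, tuple[str, str], int]] = [
    (
        "CUB",
        "Other effects of climate change have been observed or measured in the "
        "sectors of agriculture and human health, as well as biodiversity",
        ("impact", "general"), 1,
    ),
    (
        "KHM",
        "Examples of direct impacts include death, injury, psychological "
        "disorders, and damage to public health infrastructure",
        ("impact", "specific"), 3,
    ),
    (
        "SLV",
        "El Salvador has resorted to sectoral adaptation strategies with an "
        "emphasis on agriculture, resources, infrastructure and health, "
        "contained in the National Strategy for Climate Change and in the "
        "Plan National Climate Change",
        ("adaptation", "general"), 2,
    ),
    (
        "BTN",
        "Minimize climate-related health risks through: strengthening "
        "integrated risk monitoring and early warning systems and response "
        "for climate sensitive diseases",
        ("adaptation", "detailed"), 3,
    ),
    (
        "CHL",
        "This strategy seeks to articulate and link effective energy and "
        "environmental plans by establishing goals and objectives in the area "
        "of energy, water, waste, and health for the short, medium, and "
        "long-term",
        ("mitigation", "general"), 2,
    ),
    (
        "MEX",
        "Regarding mitigation, sets a clear obligation to give priority to "
        "the least costly mitigation actions, that at the same time derived "
        "in health and well-being co-benefits to the Mexican population",
        ("co_benefit", "general"), 2,
    ),
    (
        "LSO",
        "Create a market for clean and efficient household cooking solutions "
        "in order to save lives, improve livelihoods, empower women, and "
        "protect the environment",
        ("co_benefit", "specific"), 3,
    ),
    (
        "GHA",
        "As a developing country, the lack of fiscal space to finance "
        "priority issues including poverty reduction policies including "
        "investments in education, health, and basic infrastructure "
        "constrains the country's effort to finance and implement climate "
        "mitigation and adaptation policies",
        ("trade_off", "general"), 2,
    ),
    (
        "GNQ",
        "Equatorial Guinea is a developing country, whose economy depends "
        "exclusively on extractive industries and has to face a series of "
        "development challenges, such as: poverty, education, health, road "
        "infrastructure, etc",
        ("background", "general"), 1,
    ),
]


@pytest.fixture(scope="session")
def lexicon() -> HealthLexicon:
    return HealthLexicon.default()


@pytest.fixture(scope="session")
def preprocess() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture()
def make_tokenized(preprocess):
    """Factory turning raw text into a TokenizedDocument."""

    def _make(text: str, doc_id: str = "DOC"):
        return tokenize(Document(doc_id=doc_id, text=text), preprocess)

    return _make
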