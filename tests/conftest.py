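import pytest

import dxcollect as dx


@pytest.fixture(scope="session")
def tiny_term() -> dx.Terminology:
    """Hand-built terminology exercising synonyms, tags and duplicates."""
    concepts = [
        dx.Concept("C001", "Chlamydial infection (disorder)",
                   ("Chlamydial infection (disorder)", "Chlamydia infection",
                    "Chlamydia infections"), "disorder"),
        dx.Concept("C002", "HIV infection (disorder)",
                   ("HIV infection (disorder)", "HIV infection"), "disorder"),
        dx.Concept("C003", "Lung tumor",
                   ("Lung tumor", "Tumour of lung"), "disorder"),
        # C004/C005 share a normalized token set but differ in tag:
        dx.Concept("C004", "Cardiac murmur", ("Cardiac murmur",), "finding"),
        dx.Concept("C005", "Murmur cardiac", ("Murmur cardiac",), "disorder"),
        dx.Concept("C006", "Anemia", ("Anemia", "Anaemia"), "disorder"),
        dx.Concept("C007", "Myocardial infarction",
                   ("Myocardial infarction", "Heart attack"), "disorder"),
    ]
    return dx.Terminology.from_concepts(concepts)


@pytest.fixture(scope="session")
def small_world() -> dx.World:
    """Mixed human/LLM cohort reused across experiment-level tests."""
    profiles = tuple(
        [dx.DiagnosticianProfile(f"H{i}", "human", 0.45, 0.6, 0.5,
                                 error_pool="human") for i in range(6)]
        + [dx.DiagnosticianProfile("LLM0", "llm", 0.6, 0.7, 0.5,
                                   error_pool="llm"),
           dx.DiagnosticianProfile("LLM1", "llm", 0.35, 0.7, 0.5,
                                   error_pool="llm")]
    )
    cfg = dx.WorldConfig(seed=11, n_cases=80, n_concepts=150,
                         profiles=profiles)
    return dx.generate_world(cfg)
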