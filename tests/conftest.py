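import numpy as np
import pytest

from cogtype import fmi, linguistic, simulate

# The worked eight-word example sentence: 'grandmother' (token 4) is the
# root heading 'I', 'am', 'the' and 'grandson'; 'grandson' (token 8) heads
# 'of', 'a' and 'wonderful'.  Link distances 3+2+1+4+3+2+1 = 16 over 7
# non-root tokens.
FIG1_CONLLU = """\
# sent_id = example-1
1\tI\tI\tPRON\t_\t_\t4\tnsubj\t_\t_
2\tam\tam\tAUX\t_\t_\t4\tcop\t_\t_
3\tthe\tthe\tDET\t_\t_\t4\tdet\t_\t_
4\tgrandmother\tgrandmother\tNOUN\t_\t_\t0\troot\t_\t_
5\tof\tof\tADP\t_\t_\t8\tcase\t_\t_
6\ta\ta\tDET\t_\t_\t8\tdet\t_\t_
7\twonderful\twonderful\tADJ\t_\t_\t8\tamod\t_\t_
8\tgrandson\tgrandson\tNOUN\t_\t_\t4\tnmod\t_\t_
"""


@pytest.fixture(scope="session")
def fig1_doc() -> linguistic.ParsedDocument:
    doc = linguistic.parse_conllu(FIG1_CONLLU, doc_id="example", subject_id="u1")
    assert doc is not None
    return doc


@pytest.fixture(scope="session")
def severity_samples() -> list[fmi.SeveritySample]:
    """The severity recovery dataset: 30 subjects x 20 sessions, fixed seed."""
    return simulate.simulate_severity_dataset(
        simulate.SeverityGeneratorSpec(n_subjects=30, sessions_per_subject=20,
                                       seed=7)
    )


@pytest.fixture(scope="session")
def severity_fit(severity_samples) -> fmi.FinetuneResult:
    """Pretrained + LOSO fine-tuned severity models (shared: expensive)."""
    cfg = fmi.TrainingConfig(seed=11)
    pre = fmi.pretrain_autoencoder(
        [s.dynamics for s in severity_samples], cfg=cfg
    )
    return fmi.finetune_regressors(pre, severity_samples)


def random_document(rng: np.random.Generator) -> linguistic.ParsedDocument:
    """A small random parsed document for oracle comparisons."""
    params = simulate.DocParams(
        zipf_exponent=float(rng.uniform(0.8, 1.6)),
        stop_rate=float(rng.uniform(0.1, 0.6)),
        noun_rate=float(rng.uniform(0.1, 0.5)),
        verb_rate=float(rng.uniform(0.1, 0.4)),
        pron_rate=float(rng.uniform(0.02, 0.3)),
        attach_p=float(rng.uniform(0.2, 0.95)),
        n_sents_mean=float(rng.uniform(2, 8)),
        words_per_sent_mean=float(rng.uniform(4, 14)),
    )
    return simulate.simulate_document(params, rng)
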