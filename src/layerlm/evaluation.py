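"""Average precision and MAP over TREC-style runs and qrels.

Binary relevance (grade >= 1); AP is normalized by the total number of
relevant documents even when the run retrieves fewer, matching the
trec_eval convention.  Topics with no relevant document are skipped, not
scored zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .annotation_io import Qrels

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    per_topic_ap: Dict[str, float] = field(default_factory=dict)
    map_score: float = 0.0
    topics_evaluated: int = 0
    topics_skipped: int = 0

    def as_dict(self) -> dict:
        return {
            "MAP": self.map_score,
            "topics_evaluated": self.topics_evaluated,
            "topics_skipped": self.topics_skipped,
            "per_topic_ap": dict(sorted(self.per_topic_ap.items())),
        }


def average_precision(ranked_doc_ids: Sequence[str], relevant: Set[str]) -> float:
    """AP = (1/R) * sum over relevant retrieved docs of precision@rank.

    Relevant docs absent from the ranking contribute 0.  Raises on an
    empty relevant set (the caller decides how to skip such topics) and on
    duplicate doc ids in the ranking.
    """
    if not relevant:
        raise ValueError("average_precision undefined with no relevant documents")
    if len(set(ranked_doc_ids)) != len(ranked_doc_ids):
        raise ValueError("ranking contains duplicate doc ids")
    hits = 0
    total = 0.0
    for rank, doc_id in enumerate(ranked_doc_ids, start=1):
        if doc_id in relevant:
            hits += 1
            total += hits / rank
    return total / len(relevant)


def evaluate_run(
    run: Dict[str, Sequence[Tuple[str, float]]] | Dict[str, Sequence[str]],
    qrels: Qrels,
) -> EvalReport:
    """Per-topic AP and MAP for a run against judgments.

    ``run`` maps topic -> ranked doc ids (optionally (doc_id, score) pairs).
    Topics judged in the qrels but missing from the run score AP = 0;
    topics without any relevant document are skipped.
    """
    report = EvalReport()
    ap_values: List[float] = []
    for topic in qrels.topics():
        relevant = qrels.relevant_docs(topic)
        if not relevant:
            logger.info("topic %s skipped: no relevant documents", topic)
            report.topics_skipped += 1
            continue
        entries = run.get(topic, [])
        ranked = [e[0] if isinstance(e, (tuple, list)) else e for e in entries]
        ap = average_precision(ranked, relevant) if ranked else 0.0
        report.per_topic_ap[topic] = ap
        ap_values.append(ap)
        report.topics_evaluated += 1
    report.map_score = sum(ap_values) / len(ap_values) if ap_values else 0.0
    return report
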