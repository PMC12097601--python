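"""Dialogue contract for chat-based (LLM) players.

A backend is any callable ``prompt text -> reply text`` — a live chat API or
a scripted mock.  Each round the agent is prompted for a single action.  A
reply is parsed preferentially from a structured ``ANSWER: C`` / ``ANSWER: D``
line; otherwise a free-text reply parses only if it mentions exactly one of
the cooperate/defect keyword families.  Unparseable replies trigger a
clarification re-prompt; after three failed attempts the experiment is
deemed a failure and interrupted (the engine marks the log ``failed``).

No live provider is bundled; tests run mock-only.  Provider credentials, if
a live backend is wired in, come from environment variables outside this
module.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .agents import C, D, AgentSpec, ContractError, Observation
from .engine import AgentFailureError

__all__ = [
    "DialogueTranscript",
    "parse_action",
    "render_prompt",
    "query_agent",
    "llm_act",
    "ScriptedBackend",
    "transcripts_to_jsonl",
    "MAX_ATTEMPTS",
    "DEFAULT_PROMPT_TEMPLATE",
]

MAX_ATTEMPTS = 3

# The template casts the model as a human participant in the repeated game
# and requests a structured one-line answer it can parse deterministically.
DEFAULT_PROMPT_TEMPLATE = (
    "You are emulating a human participant in a repeated economic game.\n"
    "Each round you choose one action: C (pay 10 points per neighbor so each "
    "neighbor gains a larger benefit) or D (do nothing).\n"
    "This is round {round}. You have {degree} neighbors.\n"
    "{history}\n"
    "Choose your action for this round. Reply with exactly one line:\n"
    "ANSWER: C  or  ANSWER: D"
)

CLARIFICATION = (
    "Your previous reply did not state a clear action. "
    "Reply with exactly one line: 'ANSWER: C' or 'ANSWER: D'."
)

_ANSWER_RE = re.compile(r"ANSWER\s*[:\-]?\s*\b(C|D)\b", re.IGNORECASE)
_COOP_RE = re.compile(r"\bcooperat\w*\b|\bC\b", re.IGNORECASE)
_DEFECT_RE = re.compile(r"\bdefect\w*\b|\bD\b", re.IGNORECASE)


@dataclass
class DialogueTranscript:
    """Full record of one action query (all attempts)."""

    player: int
    round: int
    prompts: List[str] = field(default_factory=list)
    replies: List[str] = field(default_factory=list)
    parsed_action: Optional[str] = None
    attempts: int = 0
    failed: bool = False

    def to_dict(self) -> dict:
        return {
            "player": self.player,
            "round": self.round,
            "prompts": self.prompts,
            "replies": self.replies,
            "parsed_action": self.parsed_action,
            "attempts": self.attempts,
            "failed": self.failed,
        }


def parse_action(reply: str) -> Optional[str]:
    """Extract C or D from a reply, or None when unparseable.

    A structured ``ANSWER: C/D`` line wins.  Otherwise the reply parses only
    when exactly one of the keyword families (cooperate/C vs defect/D) is
    mentioned; both or neither is unparseable.
    """
    m = _ANSWER_RE.search(reply)
    if m:
        return m.group(1).upper()
    has_c = bool(_COOP_RE.search(reply))
    has_d = bool(_DEFECT_RE.search(reply))
    if has_c and not has_d:
        return C
    if has_d and not has_c:
        return D
    return None


def render_prompt(
    observation: Observation, template: str = DEFAULT_PROMPT_TEMPLATE
) -> str:
    if observation.round_index == 0:
        history = "This is the first round; there is no history yet."
    else:
        slots = ", ".join(
            f"slot {label}: {a}" for label, a in observation.neighbor_slots
        )
        history = (
            f"Last round your neighbors played — {slots}. "
            f"Your own last action was {observation.own_last_action} and "
            f"your last-round payoff was {observation.own_last_payoff:g} points."
        )
    return template.format(
        round=observation.round_index,
        degree=observation.degree,
        history=history,
    )


def query_agent(
    backend: Callable[[str], str],
    observation: Observation,
    prompt_template: str = DEFAULT_PROMPT_TEMPLATE,
    player: int = -1,
) -> Tuple[Optional[str], DialogueTranscript]:
    """Query a backend for one action, with up to three attempts.

    Unparseable replies and transport errors both consume an attempt and
    trigger a clarification re-prompt.  On exhaustion the action is None and
    the transcript is marked failed.
    """
    transcript = DialogueTranscript(player=player, round=observation.round_index)
    prompt = render_prompt(observation, prompt_template)
    for attempt in range(MAX_ATTEMPTS):
        transcript.prompts.append(prompt)
        transcript.attempts = attempt + 1
        try:
            reply = backend(prompt)
        except Exception as exc:  # transport error: retry within budget
            transcript.replies.append(f"<transport error: {exc}>")
            prompt = CLARIFICATION
            continue
        transcript.replies.append(reply)
        action = parse_action(reply)
        if action is not None:
            transcript.parsed_action = action
            return action, transcript
        prompt = CLARIFICATION
    transcript.failed = True
    return None, transcript


def llm_act(
    spec: AgentSpec, observation: Observation, rng: np.random.Generator
) -> str:
    """Engine-facing adapter: one action from the spec's backend.

    Raises :class:`AgentFailureError` after three unparseable attempts, which
    the engine converts into a failed experiment log.
    """
    backend = spec.backend
    if backend is None:
        raise ContractError("llm_adapter agent has no backend")
    template = spec.params.get("prompt_template", DEFAULT_PROMPT_TEMPLATE)
    action, transcript = query_agent(backend, observation, template)
    sink = getattr(backend, "transcripts", None)
    if sink is not None:
        sink.append(transcript)
    if action is None:
        raise AgentFailureError(
            f"no parseable action after {MAX_ATTEMPTS} attempts "
            f"(round {observation.round_index})"
        )
    return action


class ScriptedBackend:
    """Mock backend replaying a fixed reply sequence (cycled when exhausted).

    Records every transcript on ``self.transcripts`` so tests can inspect the
    dialogue.
    """

    def __init__(self, replies: Sequence[str]):
        if not replies:
            raise ValueError("need at least one scripted reply")
        self._replies = list(replies)
        self._cursor = 0
        self.transcripts: List[DialogueTranscript] = []

    def __call__(self, prompt: str) -> str:
        reply = self._replies[self._cursor % len(self._replies)]
        self._cursor += 1
        return reply


def transcripts_to_jsonl(transcripts: Sequence[DialogueTranscript], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(json.dumps(t.to_dict(), sort_keys=True) + "\n")
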