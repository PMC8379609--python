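"""Bundled lexical resources.

``VALENCES`` maps lowercase words to a mean polarity rating on the usual
[-4, +4] intensity scale used by social-media sentiment lexicons; the rule
scorer in :mod:`echograph.sentiment` sums the per-word valences and squashes
the total onto the [-1, +1] compound range. ``BOOSTERS`` carry an additive
intensity increment (negative entries dampen). ``NEGATIONS`` flip and damp a
following polar word. ``STOPWORDS`` is a compact English function-word list
for the topic tokenizer.
"""

VALENCES: dict[str, float] = {
    # positive
    "good": 1.9, "great": 3.1, "excellent": 2.7, "amazing": 2.8, "awesome": 3.1,
    "love": 3.2, "loved": 2.9, "like": 1.5, "best": 3.2, "better": 1.9,
    "happy": 2.7, "joy": 2.8, "glad": 2.0, "hope": 1.9, "hopeful": 2.3,
    "safe": 1.8, "safety": 1.6, "heal": 1.8, "healed": 1.9, "healthy": 2.1,
    "recover": 1.7, "recovered": 1.9, "recovery": 1.7, "cure": 1.9, "cured": 2.2,
    "win": 2.8, "winning": 2.4, "success": 2.7, "successful": 2.7, "support": 1.7,
    "supportive": 2.0, "thank": 1.9, "thanks": 1.9, "grateful": 2.4, "care": 2.2,
    "kind": 2.4, "kindness": 2.6, "brave": 2.4, "hero": 2.6, "heroes": 2.6,
    "strong": 2.3, "stronger": 2.2, "calm": 1.3, "relief": 1.9, "relieved": 2.0,
    "protect": 1.4, "protected": 1.5, "effective": 2.1, "helpful": 1.9,
    "help": 1.7, "helps": 1.7, "improve": 1.9, "improving": 1.9, "progress": 1.8,
    "optimistic": 2.2, "positive": 2.1, "wonderful": 2.7, "beautiful": 2.9,
    "trust": 2.1, "trusted": 2.1, "smart": 1.7, "wise": 2.2, "clean": 1.7,
    "free": 1.6, "freedom": 2.2, "peace": 2.5, "proud": 2.1, "celebrate": 2.7,
    "encourage": 1.9, "encouraging": 2.1, "reassuring": 1.9, "generous": 2.3,
    "fantastic": 2.6, "solid": 1.5, "fine": 0.8, "ok": 0.9, "okay": 0.9,
    # negative
    "bad": -2.5, "worse": -2.1, "worst": -3.1, "terrible": -2.1, "horrible": -2.5,
    "awful": -2.0, "hate": -2.7, "hated": -2.4, "fear": -2.2, "feared": -2.0,
    "afraid": -2.2, "scared": -2.2, "scary": -2.2, "scare": -2.2, "panic": -2.4,
    "die": -2.9, "died": -2.6, "dying": -2.9, "dead": -3.3, "death": -2.9,
    "deaths": -2.9, "deadly": -2.9, "kill": -3.2, "killed": -3.0, "kills": -3.2,
    "sick": -2.2, "sicker": -2.2, "ill": -1.8, "illness": -1.9, "disease": -1.7,
    "infected": -2.0, "infection": -1.9, "outbreak": -1.8, "epidemic": -1.9,
    "pandemic": -1.9, "crisis": -2.3, "chaos": -2.5, "disaster": -2.9,
    "catastrophe": -3.0, "danger": -2.4, "dangerous": -2.4, "threat": -2.1,
    "risk": -1.5, "risky": -1.6, "worry": -1.9, "worried": -1.9, "worrying": -1.9,
    "anxious": -1.9, "anxiety": -2.0, "stress": -1.9, "stressed": -2.0,
    "suffer": -2.3, "suffering": -2.4, "pain": -2.3, "painful": -2.4,
    "lose": -1.9, "losing": -2.0, "lost": -1.7, "loss": -1.9, "fail": -2.3,
    "failed": -2.3, "failure": -2.4, "lie": -1.9, "lies": -1.9, "liar": -2.6,
    "fake": -2.1, "hoax": -2.2, "fraud": -2.7, "corrupt": -2.7, "blame": -1.9,
    "angry": -2.3, "anger": -2.4, "furious": -2.8, "sad": -2.1, "sadly": -1.9,
    "cry": -1.9, "crying": -2.0, "terror": -2.7, "terrifying": -2.8,
    "horror": -2.7, "wrong": -1.6, "problem": -1.4, "problems": -1.5,
    "shortage": -1.7, "collapse": -2.2, "crash": -2.1, "warn": -1.4,
    "warning": -1.4, "victim": -1.8, "victims": -1.9, "quarantine": -1.2,
    "lockdown": -1.1, "ban": -1.5, "banned": -1.6, "cancel": -1.3,
    "cancelled": -1.4, "shut": -1.1, "emergency": -1.9, "severe": -1.9,
    "critical": -1.5, "toxic": -2.3, "useless": -1.9, "stupid": -2.4,
    "dumb": -2.3, "shame": -2.1, "disgusting": -2.7, "evil": -3.1,
}

BOOSTERS: dict[str, float] = {
    "very": 0.293, "really": 0.293, "extremely": 0.293, "absolutely": 0.293,
    "incredibly": 0.293, "totally": 0.293, "completely": 0.293, "so": 0.293,
    "hugely": 0.293, "highly": 0.293, "deeply": 0.293, "truly": 0.293,
    "quite": 0.293, "particularly": 0.293, "especially": 0.293,
    "slightly": -0.293, "somewhat": -0.293, "barely": -0.293, "hardly": -0.293,
    "marginally": -0.293, "fairly": -0.146, "rather": -0.146, "kinda": -0.293,
    "sort": -0.293, "mildly": -0.293, "almost": -0.293, "partly": -0.293,
}

NEGATIONS: frozenset[str] = frozenset({
    "not", "no", "never", "none", "neither", "nor", "nothing", "cannot",
    "cant", "dont", "doesnt", "didnt", "wont", "wouldnt", "shouldnt",
    "couldnt", "isnt", "arent", "wasnt", "werent", "aint", "without",
})

STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are as at be because been
before being below between both but by could did do does doing down during
each few for from further had has have having he her here hers herself him
himself his how i if in into is it its itself just me more most my myself of
off on once only or other our ours ourselves out over own same she should so
some such than that the their theirs them themselves then there these they
this those through to too under until up very was we were what when where
which while who whom why will with you your yours yourself yourselves s t can
don now rt via amp u r ur im ive id
""".split())
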