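# Frozen readability fixtures: texts with hand-established
# sentence/word/syllable/polysyllable counts (oracle: the packaged
# hand-syllabified dictionary plus manual sentence counting; counts
# were frozen from that oracle, independent of the tokenizer path).

FIXTURES = [{'name': 'cat_mat',
  'text': 'The cat sat on the mat.',
  'sentences': 1,
  'words': 6,
  'syllables': 6,
  'polysyllables': 0},
 {'name': 'two_simple',
  'text': 'The dog can walk. She can help.',
  'sentences': 2,
  'words': 7,
  'syllables': 7,
  'polysyllables': 0},
 {'name': 'delirium_info',
  'text': 'Delirium is a sudden change in the mind.',
  'sentences': 1,
  'words': 8,
  'syllables': 12,
  'polysyllables': 1},
 {'name': 'hospital_stay',
  'text': 'A hospital stay can be long. The staff will help you rest.',
  'sentences': 2,
  'words': 12,
  'syllables': 14,
  'polysyllables': 1},
 {'name': 'polysyllabic',
  'text': 'The medication information was important.',
  'sentences': 1,
  'words': 5,
  'syllables': 13,
  'polysyllables': 3},
 {'name': 'family_care',
  'text': 'Family can help the patient recover.',
  'sentences': 1,
  'words': 6,
  'syllables': 11,
  'polysyllables': 2},
 {'name': 'question',
  'text': 'The doctor can answer your question.',
  'sentences': 1,
  'words': 6,
  'syllables': 9,
  'polysyllables': 0},
 {'name': 'confusion',
  'text': 'Confusion and attention problems are common in delirium.',
  'sentences': 1,
  'words': 8,
  'syllables': 17,
  'polysyllables': 3},
 {'name': 'sleep',
  'text': 'Good sleep and light in the day help.',
  'sentences': 1,
  'words': 8,
  'syllables': 8,
  'polysyllables': 0},
 {'name': 'prevention',
  'text': 'Prevention of delirium is better than treatment.',
  'sentences': 1,
  'words': 7,
  'syllables': 14,
  'polysyllables': 2},
 {'name': 'three_sent',
  'text': 'The nurse was helpful. The room was calm. The night was restful.',
  'sentences': 3,
  'words': 12,
  'syllables': 14,
  'polysyllables': 0},
 {'name': 'education',
  'text': 'Education can lessen worry. Ask the team about delirium.',
  'sentences': 2,
  'words': 9,
  'syllables': 18,
  'polysyllables': 2},
 {'name': 'outcomes',
  'text': 'Some people recover early. Some need more time.',
  'sentences': 2,
  'words': 8,
  'syllables': 12,
  'polysyllables': 1},
 {'name': 'dementia',
  'text': 'Dementia is not the same as delirium.',
  'sentences': 1,
  'words': 7,
  'syllables': 12,
  'polysyllables': 2},
 {'name': 'signs',
  'text': 'Watch for sudden confusion or restless moving.',
  'sentences': 1,
  'words': 7,
  'syllables': 12,
  'polysyllables': 1},
 {'name': 'mixed_length',
  'text': 'A person with delirium may see things. Stay calm and talk in a gentle way.',
  'sentences': 2,
  'words': 15,
  'syllables': 20,
  'polysyllables': 1},
 {'name': 'long_words',
  'text': 'Hallucination and disorientation can be part of delirium.',
  'sentences': 1,
  'words': 8,
  'syllables': 20,
  'polysyllables': 3},
 {'name': 'numbers',
  'text': 'Delirium affects 1 in 3 older people in hospital.',
  'sentences': 1,
  'words': 9,
  'syllables': 17,
  'polysyllables': 2},
 {'name': 'exclaim',
  'text': 'Delirium is serious! Get help now.',
  'sentences': 2,
  'words': 6,
  'syllables': 11,
  'polysyllables': 2},
 {'name': 'question_mark',
  'text': 'Is it delirium or dementia? Ask the doctor.',
  'sentences': 2,
  'words': 8,
  'syllables': 14,
  'polysyllables': 2},
 {'name': 'abbrev',
  'text': 'Dr. Smith saw the patient.',
  'sentences': 1,
  'words': 5,
  'syllables': 6,
  'polysyllables': 0},
 {'name': 'url_noise',
  'text': 'More information is on the website. https://example.org/delirium',
  'sentences': 1,
  'words': 6,
  'syllables': 10,
  'polysyllables': 1},
 {'name': 'unterminated',
  'text': 'The ward was loud. The night felt long',
  'sentences': 2,
  'words': 8,
  'syllables': 8,
  'polysyllables': 0}]
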