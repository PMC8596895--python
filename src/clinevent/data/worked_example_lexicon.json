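{
 "has": {
  "synonyms": ["have"],
  "antonyms": [],
  "hypernyms": [],
  "hyponyms": [],
  "related_words": []
 },
 "worked": {
  "synonyms": [],
  "antonyms": [],
  "hypernyms": ["set"],
  "hyponyms": ["cut"],
  "related_words": ["put"]
 },
 "up": {
  "synonyms": [],
  "antonyms": ["down"],
  "hypernyms": [],
  "hyponyms": [],
  "related_words": []
 }
}
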