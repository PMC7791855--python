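{
 "ease_of_use": {
  "5pt": {
   "easy_very_easy": 45,
   "other": 25
  },
  "9pt": {
   "easy_very_easy": 33,
   "other": 31
  }
 },
 "clarity": {
  "5pt": {
   "clear_very_clear": 61,
   "other": 9
  },
  "9pt": {
   "clear_very_clear": 47,
   "other": 17
  }
 }
}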