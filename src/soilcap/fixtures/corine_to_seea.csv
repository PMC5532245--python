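corine_code,seea_code
111,1
112,1
121,1
122,1
123,1
124,1
131,1
132,1
133,1
141,1
142,1
211,2
212,2
213,2
221,3
222,3
223,3
231,5
241,4
242,4
243,4
244,4
311,6
312,6
313,6
321,5
322,8
323,8
324,6
331,11
332,11
333,10
334,11
335,12
411,9
412,9
421,14
422,14
423,14
511,13
512,13
521,14
522,14
523,14
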