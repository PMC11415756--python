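location,latitude,longitude,date
IJmuiden,52.451733,4.554254,2007-01-13
Westenschouwen,51.7420,3.7578,2008-11-21
Monster,52.0277,4.1591,2011-12-12
Den Helder,52.9627,4.7323,2014-12-22
Westkapelle,51.5242,3.4384,2021-12-02
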