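stage,year,n
original_posts,2015,635515709
original_posts,2016,553623151
original_posts,2017,787108543
processed_posts,2015,51019894
processed_posts,2016,49057982
processed_posts,2017,57489144
lyrics_matches,2015,61267
lyrics_matches,2016,52279
lyrics_matches,2017,37200
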