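# Default registry: the seven embedding models the audit was designed around.
# Metadata only -- vector files are large, external, and supplied by the user
# (path: null until configured). Token counts are approximate corpus sizes.
models:
  - name: internet_general
    description: English websites (UMBC WebBase, Wikipedia, SE Times news)
    medium: internet
    algorithm: fastText
    format: word2vec-text
    tokens_approx: 16e9
    time_period: "2001-2017"
    path: null
  - name: internet_news
    description: Google News articles
    medium: internet
    algorithm: word2vec
    format: word2vec-binary
    tokens_approx: 100e9
    time_period: ""
    path: null
  - name: internet_wiki_news
    description: Wikipedia 2014 + Gigaword 5 newswire
    medium: internet
    algorithm: GloVe
    format: glove-text
    tokens_approx: 5.9e9
    time_period: "1995-2014"
    path: null
  - name: internet_twitter
    description: Twitter posts (Stanford GloVe project)
    medium: social media
    algorithm: GloVe
    format: glove-text
    tokens_approx: 2e9
    time_period: ""
    path: null
  - name: tv_film
    description: Film and TV transcripts (Transcripts Wiki, Simply Scripts)
    medium: tv/film
    algorithm: fastText
    format: word2vec-text
    tokens_approx: 8.75e6
    time_period: "1938-2020"
    path: null
  - name: books
    description: Project Gutenberg books
    medium: books
    algorithm: fastText
    format: word2vec-text
    tokens_approx: 44e6
    time_period: "1820-1922"
    path: null
  - name: speech
    description: Telephone and parent-child conversation (Switchboard, CHILDES)
    medium: conversation
    algorithm: fastText
    format: word2vec-text
    tokens_approx: 11e6
    time_period: "1970-1991"
    path: null
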